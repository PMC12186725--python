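"""Readers, writers and in-memory containers for the pipeline's external formats.

Coordinate conventions: VCF and GFF3 positions are 1-based inclusive
throughout; any BED written out is 0-based half-open. Genotypes are coded as
alternate-allele dosage (0, 1, 2) with -1 for missing, one column per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("castepop")

MISSING = -1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantTable:
    """Biallelic SNP genotypes with per-sample species/population labels.

    ``genotypes`` is a (n_sites, n_samples) int8 array of alt-allele dosages
    with :data:`MISSING` (-1) for uncalled genotypes. Positions are 1-based
    and strictly increasing within each contig.
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    species: np.ndarray
    population: np.ndarray
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.contig = np.asarray(self.contig, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")
        for ctg in set(self.contig):
            p = self.pos[self.contig == ctg]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {ctg}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_mask(self, species: str | None = None, population: str | None = None) -> np.ndarray:
        m = np.ones(self.n_samples, dtype=bool)
        if species is not None:
            m &= self.species == species
        if population is not None:
            m &= self.population == population
        return m

    def take_sites(self, mask: np.ndarray) -> "VariantTable":
        return replace(
            self,
            contig=self.contig[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
        )

    def subset_samples(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            samples=[self.samples[i] for i in idx],
            species=self.species[idx],
            population=self.population[idx],
        )


@dataclass
class GeneAnnotation:
    """Strand-aware CDS model of one gene.

    ``cds_segments`` are (start, end) 1-based inclusive genomic intervals in
    transcription order: ascending coordinates for '+' genes, descending for
    '-' genes. ``phase`` is the phase of the first segment (bases to trim
    before the first complete codon). ``in_frame`` is False when the total
    phase-trimmed CDS length is not a multiple of 3; such genes are kept for
    interval analyses but excluded from codon-level ones.
    """

    gene_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int]]
    phase: int = 0
    in_frame: bool = True

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.cds_segments]
        ends = [e for _, e in self.cds_segments]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def genomic_positions(self) -> np.ndarray:
        """CDS genomic positions in transcription order (phase NOT trimmed)."""
        out = []
        for s, e in self.cds_segments:
            rng = np.arange(s, e + 1)
            if self.strand == "-":
                rng = rng[::-1]
            out.append(rng)
        return np.concatenate(out)

    def spliced_cds(self, seqs: "SequenceSet") -> str:
        """Spliced CDS nucleotide sequence in reading orientation, phase-trimmed."""
        chrom = seqs[self.contig]
        parts = []
        for s, e in self.cds_segments:
            seg = chrom[s - 1 : e]
            if self.strand == "-":
                seg = revcomp(seg)
            parts.append(seg)
        return "".join(parts)[self.phase :]


class SequenceSet(dict):
    """contig -> uppercase nucleotide string."""

    @classmethod
    def from_mapping(cls, mapping) -> "SequenceSet":
        return cls({k: str(v).upper() for k, v in mapping.items()})


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with caste/tissue/colony sample metadata."""

    counts: pd.DataFrame  # genes x samples, integer
    meta: pd.DataFrame    # samples x {caste, tissue, colony}

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count columns and metadata rows disagree")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class AnalysisConfig:
    """Thresholds and rates used across the pipeline.

    ``min_called_alleles`` is the completeness filter on the number of called
    alleles (AN) at a site; ``mu_low``/``mu_high`` bracket the per-site
    per-generation mutation rate used for divergence dating (honey bee and
    bumble bee direct estimates).
    """

    window_bp: int = 10_000
    maf_min: float = 0.05
    min_called_alleles: int = 50
    ld_r2_max: float = 0.8
    ld_window_bp: int = 500_000
    ld_step_bp: int = 1_000
    fst_fixed_threshold: float = 0.95
    fst_high_threshold: float = 0.90
    min_cds_snps: int = 3
    mu_low: float = 3.4e-9
    mu_high: float = 3.6e-9
    de_alpha: float = 0.05
    de_lfc_threshold: float = 1.0
    roh_min_snps: int = 50
    roh_max_het: int = 1
    roh_min_bp: int = 100_000
    fixed_diff_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min out of range")
        if self.mu_low <= 0 or self.mu_high < self.mu_low:
            raise ValueError("bad mutation-rate bracket")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample_sheet: pd.DataFrame) -> VariantTable:
    """Load biallelic SNPs from a VCF 4.x file.

    ``sample_sheet`` must carry columns ``sample``, ``species``,
    ``population`` covering every VCF sample. Multiallelic records and
    indels are skipped (counted in ``filter_report``); half-called
    genotypes are treated as missing.
    """
    from cyvcf2 import VCF

    sheet = sample_sheet.set_index("sample")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sheet.index]
    if unknown:
        raise ValueError(f"samples missing from sheet: {unknown}")

    contig, pos, ref, alt, rows = [], [], [], [], []
    skipped = {"multiallelic": 0, "indel": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        # gts012=True codes genotypes as alt dosage with 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        contig.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        rows.append(g)
    logger.info("read_vcf: %d sites kept, skipped %s", len(pos), skipped)
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return VariantTable(
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=geno,
        samples=samples,
        species=sheet.loc[samples, "species"].to_numpy(dtype=object),
        population=sheet.loc[samples, "population"].to_numpy(dtype=object),
        filter_report={"skipped": skipped},
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ctg in dict.fromkeys(vt.contig):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in vt.genotypes[i])
            fh.write(f"{vt.contig[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3 / FASTA / tables


def read_gff3(path) -> list[GeneAnnotation]:
    """Parse gene models from GFF3, one annotation per gene.

    The longest-CDS mRNA represents a gene with several transcripts.
    Minus-strand segments are reordered to transcription order. Genes whose
    phase-trimmed CDS length is not a multiple of 3 are flagged
    ``in_frame=False``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            if not cds:
                continue
            total = sum(c.end - c.start + 1 for c in cds)
            if best is None or total > best[0]:
                best = (total, cds)
        if best is None:
            cds = list(db.children(gene, featuretype="CDS"))
            if not cds:
                continue
            best = (sum(c.end - c.start + 1 for c in cds), cds)
        _, cds = best
        cds.sort(key=lambda c: c.start)
        if gene.strand == "-":
            cds = cds[::-1]
        first_phase = cds[0].frame
        phase = int(first_phase) if first_phase not in (None, ".") else 0
        segs = [(c.start, c.end) for c in cds]
        length = sum(e - s + 1 for s, e in segs) - phase
        ann = GeneAnnotation(
            gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
            cds_segments=segs, phase=phase, in_frame=length % 3 == 0,
        )
        if not ann.in_frame:
            logger.warning("gene %s CDS length %d not a multiple of 3", gene.id, length)
        genes.append(ann)
    return genes


def write_gff3(genes: list[GeneAnnotation], contig_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ctg, ln in contig_lengths.items():
            fh.write(f"##sequence-region {ctg} 1 {ln}\n")
        for g in genes:
            lo, hi = g.span
            fh.write(f"{g.contig}\tcastepop\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\tcastepop\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            # phase per segment follows from cumulative length in transcription order
            order = sorted(g.cds_segments)
            if g.strand == "-":
                order = order[::-1]
            lines, cum = {}, 0
            for s, e in order:
                ph = g.phase if cum == 0 else (3 - ((cum - g.phase) % 3)) % 3
                lines[(s, e)] = ph
                cum += e - s + 1
            for s, e in sorted(lines):
                fh.write(
                    f"{g.contig}\tcastepop\tCDS\t{s}\t{e}\t.\t{g.strand}\t{lines[(s, e)]}"
                    f"\tID={mid}.cds;Parent={mid}\n"
                )


def read_fasta(path) -> SequenceSet:
    from Bio import SeqIO

    return SequenceSet({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_counts(path, metadata: pd.DataFrame) -> ExpressionMatrix:
    """Read a TSV count matrix (gene rows, sample columns) plus metadata.

    ``metadata`` is indexed by sample id with columns caste/tissue/colony.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise ValueError("duplicated gene ids in count matrix")
    vals = counts.to_numpy()
    if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    meta = metadata.loc[counts.columns]
    return ExpressionMatrix(counts=counts, meta=meta)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "species", "population"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return sheet


def read_orthologs(path) -> dict[str, str]:
    """One-to-one ortholog map (reciprocal best hits) from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"])
    if df.gene_a.duplicated().any() or df.gene_b.duplicated().any():
        raise ValueError("ortholog map is not one-to-one")
    return dict(zip(df.gene_a, df.gene_b))


# ---------------------------------------------------------------------------
# BED (0-based half-open on output)


def cds_to_bed(genes: list[GeneAnnotation]) -> pd.DataFrame:
    rows = [
        {"chrom": g.contig, "start": s - 1, "end": e, "name": g.gene_id, "strand": g.strand}
        for g in genes
        for s, e in sorted(g.cds_segments)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def bed_to_intervals(bed: pd.DataFrame) -> list[tuple[str, int, int, str]]:
    """BED rows back to 1-based inclusive (chrom, start, end, name)."""
    return [(r.chrom, int(r.start) + 1, int(r.end), r.name) for r in bed.itertuples()]
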