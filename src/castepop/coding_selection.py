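"""Codon-aware SNP classification and per-gene selection statistics.

Covers synonymous/nonsynonymous classification against the reference codon,
polarization of sites into focal-species polymorphisms vs fixed
interspecies differences, McDonald-Kreitman tables with the Neutrality
Index NI = (Pn/Ps)/(Dn/Ds) and Direction of Selection
DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps), Nei-Gojobori (1986) dN/dS with
Jukes-Cantor correction, and simple per-gene features (GC%, CDS length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import MISSING, GeneAnnotation, SequenceSet, VariantTable, revcomp

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    """Single-letter amino acid, '*' for stop."""
    return "*" if codon in STOP_CODONS else CODON_TABLE[codon]


@dataclass
class SiteEffect:
    contig: str
    pos: int
    gene_id: str
    codon_index: int      # 0-based codon along the (phase-trimmed) CDS
    codon_position: int   # 1-3 within the codon
    effect: str           # synonymous | nonsynonymous | nonsense | noncoding


@dataclass
class MKTable:
    gene_id: str
    Pn: int = 0
    Ps: int = 0
    Dn: int = 0
    Ds: int = 0
    NI: float = math.nan
    neglog2_NI: float = math.nan
    DoS: float = math.nan
    dN: float = math.nan
    dS: float = math.nan
    dNdS: float = math.nan
    flags: tuple = ()


class GeneCodonIndex:
    """Precomputed mapping from genomic position to CDS/codon coordinates."""

    def __init__(self, gene: GeneAnnotation, seqs: SequenceSet):
        self.gene = gene
        self.cds = gene.spliced_cds(seqs)
        gpos = gene.genomic_positions()[gene.phase :]
        usable = len(self.cds) - len(self.cds) % 3
        self.cds = self.cds[:usable]
        self.index = {int(p): i for i, p in enumerate(gpos[:usable])}

    def classify(self, pos: int, ref: str, alt: str) -> SiteEffect:
        g = self.gene
        i = self.index.get(pos)
        if i is None:
            return SiteEffect(g.contig, pos, g.gene_id, -1, 0, "noncoding")
        ref_t = ref if g.strand == "+" else revcomp(ref)
        alt_t = alt if g.strand == "+" else revcomp(alt)
        if self.cds[i] != ref_t:
            raise ValueError(
                f"reference mismatch at {g.contig}:{pos} in {g.gene_id}: "
                f"CDS has {self.cds[i]}, VCF ref (transcribed) {ref_t}"
            )
        ci, cp = divmod(i, 3)
        codon = self.cds[3 * ci : 3 * ci + 3]
        mutated = codon[:cp] + alt_t + codon[cp + 1 :]
        aa0, aa1 = translate_codon(codon), translate_codon(mutated)
        if aa1 == aa0:
            effect = "synonymous"
        elif aa1 == "*" and aa0 != "*":
            effect = "nonsense"
        else:
            effect = "nonsynonymous"
        return SiteEffect(g.contig, pos, g.gene_id, ci, cp + 1, effect)


def classify_site(
    seqs: SequenceSet, gene: GeneAnnotation, pos: int, ref: str, alt: str
) -> SiteEffect:
    """Effect of substituting ``alt`` for ``ref`` at 1-based ``pos`` in ``gene``."""
    return GeneCodonIndex(gene, seqs).classify(pos, ref, alt)


# ---------------------------------------------------------------------------
# polarization


def polarize_sites(
    vt: VariantTable, focal_species: str, sister_species: str, fixed_tolerance: float = 0.0
) -> pd.DataFrame:
    """Per-site status: polymorphic_focal / fixed_difference / shared_or_other.

    A fixed difference requires the focal species fixed for one allele and
    the sister fixed for the other (allele-frequency departure up to
    ``fixed_tolerance`` allowed). Sites segregating in the sister as well as
    the focal are 'shared_or_other' but still count as focal polymorphism
    (``counts_as`` = P); they never count as divergence. Sites with no
    called focal (or sister) genotypes are excluded.
    """
    mf = vt.sample_mask(species=focal_species)
    ms = vt.sample_mask(species=sister_species)
    gf, gs = vt.genotypes[:, mf], vt.genotypes[:, ms]
    cf, cs = gf != MISSING, gs != MISSING
    nf, ns = 2 * cf.sum(axis=1), 2 * cs.sum(axis=1)
    df_, ds_ = np.where(cf, gf, 0).sum(axis=1), np.where(cs, gs, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pf = np.where(nf > 0, df_ / np.maximum(nf, 1), np.nan)
        ps = np.where(ns > 0, ds_ / np.maximum(ns, 1), np.nan)
    tol = fixed_tolerance
    focal_seg = (df_ > 0) & (df_ < nf)
    sister_seg = (ds_ > 0) & (ds_ < ns)
    focal_fixed_alt = pf >= 1 - tol
    focal_fixed_ref = pf <= tol
    sister_fixed_alt = ps >= 1 - tol
    sister_fixed_ref = ps <= tol
    fixed_diff = (focal_fixed_alt & sister_fixed_ref) | (focal_fixed_ref & sister_fixed_alt)
    status = np.full(vt.n_sites, "shared_or_other", dtype=object)
    status[fixed_diff & ~focal_seg] = "fixed_difference"
    status[focal_seg & ~sister_seg] = "polymorphic_focal"
    counts_as = np.full(vt.n_sites, "none", dtype=object)
    counts_as[status == "fixed_difference"] = "D"
    counts_as[focal_seg] = "P"
    excluded = (nf == 0) | (ns == 0)
    status[excluded] = "excluded"
    counts_as[excluded] = "none"
    return pd.DataFrame(
        {"contig": vt.contig, "pos": vt.pos, "status": status, "counts_as": counts_as}
    )


# ---------------------------------------------------------------------------
# MK table


def mk_statistics(Pn: int, Ps: int, Dn: int, Ds: int) -> tuple[float, float, float, tuple]:
    """(NI, -log2 NI, DoS, flags) from the four MK counts."""
    flags = []
    if Ps > 0 and Dn > 0 and Pn >= 0 and Ds > 0:
        ni = (Pn / Ps) / (Dn / Ds)
        nlog = -math.log2(ni) if ni > 0 else math.inf
        if ni == 0:
            flags.append("ni_zero")
    else:
        ni, nlog = math.nan, math.nan
        flags.append("ni_undefined")
    if (Dn + Ds) > 0 and (Pn + Ps) > 0:
        dos = Dn / (Dn + Ds) - Pn / (Pn + Ps)
    else:
        dos = math.nan
        flags.append("dos_undefined")
    return ni, nlog, dos, tuple(flags)


def _mk_from_effects(
    gene: GeneAnnotation,
    effects: list[SiteEffect],
    pol_counts: dict,
    count_nonsense_as_nonsyn: bool = True,
) -> MKTable:
    tally = {"Pn": 0, "Ps": 0, "Dn": 0, "Ds": 0}
    for eff in effects:
        if eff.effect == "noncoding":
            continue
        kind = eff.effect
        if kind == "nonsense":
            if not count_nonsense_as_nonsyn:
                continue
            kind = "nonsynonymous"
        cas = pol_counts.get((eff.contig, eff.pos))
        if cas == "P":
            tally["Pn" if kind == "nonsynonymous" else "Ps"] += 1
        elif cas == "D":
            tally["Dn" if kind == "nonsynonymous" else "Ds"] += 1
    ni, nlog, dos, flags = mk_statistics(**tally)
    return MKTable(gene_id=gene.gene_id, **tally, NI=ni, neglog2_NI=nlog, DoS=dos, flags=flags)


def mk_table(
    gene: GeneAnnotation,
    effects: list[SiteEffect],
    polarization: pd.DataFrame,
    count_nonsense_as_nonsyn: bool = True,
) -> MKTable:
    """Per-gene Pn/Ps/Dn/Ds and derived NI, -log2 NI, DoS.

    ``effects`` are classified coding sites of this gene; ``polarization``
    supplies counts_as (P/D/none) keyed by (contig, pos).
    """
    pol_counts = dict(zip(zip(polarization.contig, polarization.pos), polarization.counts_as))
    return _mk_from_effects(gene, effects, pol_counts, count_nonsense_as_nonsyn)


# ---------------------------------------------------------------------------
# NG86 dN/dS


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes creating stops count as nonsynonymous.
    """
    syn = 0.0
    aa = translate_codon(codon)
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if translate_codon(mut) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over all
    mutational pathways that avoid stop-codon intermediates (all pathways if
    every one passes through a stop)."""
    pos = [p for p in range(3) if c1[p] != c2[p]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in permutations(pos):
        cur, syn, non, ok = c1, 0.0, 0.0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if translate_codon(nxt) == "*" and len(pos) > 1:
                ok = False
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((syn, non, ok))
    valid = [(s, n) for s, n, ok in results if ok]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); nan at p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def dnds_ng86(cds_a: str, cds_b: str) -> tuple[float, float, float, tuple]:
    """Nei-Gojobori dN, dS and their ratio for two aligned in-frame CDSs.

    Returns (dN, dS, dN/dS, flags); the ratio is nan when dS = 0 or a
    Jukes-Cantor correction is undefined. Codons containing N or reference
    stops are skipped.
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    flags = []
    if S == 0 or N == 0:
        return math.nan, math.nan, math.nan, ("no_sites",)
    ps, pn = Sd / S, Nd / N
    dS, dN = jukes_cantor(ps), jukes_cantor(pn)
    if math.isnan(dS) or math.isnan(dN):
        flags.append("jc_saturated")
    if dS and not math.isnan(dS) and not math.isnan(dN):
        ratio = dN / dS
    else:
        ratio = math.nan
        if dS == 0:
            flags.append("ds_zero")
    return dN, dS, ratio, tuple(flags)


def species_consensus_cds(
    gene: GeneAnnotation,
    seqs: SequenceSet,
    vt: VariantTable,
    species: str,
    idx: "GeneCodonIndex | None" = None,
    site_rows: np.ndarray | None = None,
) -> str:
    """Spliced CDS with each site replaced by the species' majority allele.

    Ties and all-missing sites fall back to the reference base.
    ``idx``/``site_rows`` allow reuse of a prebuilt codon index and the row
    indices of the gene's variant sites.
    """
    idx = GeneCodonIndex(gene, seqs) if idx is None else idx
    m = vt.sample_mask(species=species)
    g = vt.genotypes[:, m]
    called = g != MISSING
    n = 2 * called.sum(axis=1)
    d = np.where(called, g, 0).sum(axis=1)
    cds = list(idx.cds)
    if site_rows is None:
        site_rows = np.flatnonzero(vt.contig == gene.contig)
    for i in site_rows:
        j = idx.index.get(int(vt.pos[i]))
        if j is None or n[i] == 0:
            continue
        if d[i] * 2 > n[i]:  # alt is the majority allele
            alt = vt.alt[i] if gene.strand == "+" else revcomp(vt.alt[i])
            cds[j] = alt
    return "".join(cds)


# ---------------------------------------------------------------------------
# gene features


def gene_features(
    seqs: SequenceSet, gene: GeneAnnotation, phylostratum: str | None = None
) -> dict:
    """GC% over the genomic gene span (introns included), CDS-only GC%,
    effective length (= summed CDS length), and the consumed phylostratum."""
    lo, hi = gene.span
    span_seq = seqs[gene.contig][lo - 1 : hi]
    cds_seq = "".join(seqs[gene.contig][s - 1 : e] for s, e in sorted(gene.cds_segments))

    def gc(s: str) -> float:
        acgt = sum(s.count(b) for b in "ACGT")
        return 100.0 * (s.count("G") + s.count("C")) / acgt if acgt else math.nan

    return {
        "gene_id": gene.gene_id,
        "gc_percent": gc(span_seq),
        "gc_percent_cds": gc(cds_seq),
        "effective_length": gene.cds_length,
        "phylostratum": phylostratum,
    }


def mk_tables_for_genes(
    vt: VariantTable,
    seqs: SequenceSet,
    genes: list[GeneAnnotation],
    focal_species: str,
    sister_species: str,
    fixed_tolerance: float = 0.0,
) -> pd.DataFrame:
    """One MK/dNdS row per in-frame gene; out-of-frame genes are skipped."""
    pol = polarize_sites(vt, focal_species, sister_species, fixed_tolerance)
    pol_counts = dict(zip(zip(pol.contig, pol.pos), pol.counts_as))
    by_contig = {ctg: np.flatnonzero(vt.contig == ctg) for ctg in dict.fromkeys(vt.contig)}
    rows = []
    for gene in genes:
        if not gene.in_frame:
            continue
        idx = GeneCodonIndex(gene, seqs)
        ctg_rows = by_contig.get(gene.contig, np.empty(0, int))
        lo, hi = gene.span
        sub = ctg_rows[(vt.pos[ctg_rows] >= lo) & (vt.pos[ctg_rows] <= hi)]
        effects = [
            idx.classify(int(vt.pos[i]), vt.ref[i], vt.alt[i])
            for i in sub
            if int(vt.pos[i]) in idx.index
        ]
        mk = _mk_from_effects(gene, effects, pol_counts)
        ca = species_consensus_cds(gene, seqs, vt, focal_species, idx=idx, site_rows=sub)
        cb = species_consensus_cds(gene, seqs, vt, sister_species, idx=idx, site_rows=sub)
        dn, ds, ratio, flags = dnds_ng86(ca, cb)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "Pn": mk.Pn, "Ps": mk.Ps, "Dn": mk.Dn, "Ds": mk.Ds,
                "NI": mk.NI, "neglog2_NI": mk.neglog2_NI, "DoS": mk.DoS,
                "dN": dn, "dS": ds, "dNdS": ratio,
                "flags": ";".join(mk.flags + flags),
            }
        )
    return pd.DataFrame(rows)
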