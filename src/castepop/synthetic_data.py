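"""Two-species, multi-population synthetic data with known selection regimes.

The generator emulates the data structure of a two-species stingless-bee
population-genomic study: a reference genome of protein-coding genes,
biallelic SNPs for two species that split T_s generations ago (one
generation per year), within-species population structure following the
Balding-Nichols model, per-gene selection regimes shaping the balance of
synonymous/nonsynonymous polymorphism and divergence, and caste-structured
negative-binomial RNA-seq counts.

Sites are independent (no linkage); fixed interspecies differences follow
their deterministic expectation L * 2*mu*T_s; sweeps are modelled only as
extra fixed nonsynonymous differences plus locally elevated differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (
    MISSING,
    ExpressionMatrix,
    GeneAnnotation,
    SequenceSet,
    VariantTable,
    revcomp,
)

SPECIES = ("carbonaria", "hockingsi")
POPULATIONS = {
    "carbonaria": ("carb_north", "carb_south"),
    "hockingsi": ("hock_north", "hock_south"),
}
CASTES = ("queen", "male", "forager", "innest_worker")
TISSUES = ("head", "abdomen")


@dataclass
class Regime:
    """Per-gene-class selection regime.

    ``f_del`` is the fraction of nonsynonymous mutations removed by
    purifying selection (applied identically to polymorphism and
    divergence); ``k_sweeps`` adds that many extra fixed nonsynonymous
    differences per gene; ``f_local`` optionally overrides the
    Balding-Nichols F at the gene's polymorphic sites (recurrent local
    selection raising differentiation).
    """

    kind: str = "purifying"  # neutral | purifying | relaxed | positive
    f_del: float = 0.8
    k_sweeps: int = 0
    f_local: float | None = None


def neutral_regime() -> Regime:
    return Regime(kind="neutral", f_del=0.0)


def purifying_regime(f_del: float = 0.8) -> Regime:
    return Regime(kind="purifying", f_del=f_del)


def relaxed_regime(f_del: float = 0.1) -> Regime:
    return Regime(kind="relaxed", f_del=f_del)


def positive_regime(k_sweeps: int = 3, f_local: float = 0.45, f_del: float = 0.0) -> Regime:
    return Regime(kind="positive", f_del=f_del, k_sweeps=k_sweeps, f_local=f_local)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-species dataset.

    Defaults mirror the real system's scale: split time ~0.6 Ma at one
    generation per year with mu ~3.5e-9 (so 2*mu*T_s ~ 0.0042, matching the
    observed interspecies dxy), per-species polymorphic-site density giving
    pi of a few per mille, and moderate within-species differentiation.
    """

    n_genes_per_class: dict = field(
        default_factory=lambda: {"queen_biased": 100, "worker_biased": 100, "unbiased": 100}
    )
    regimes: dict = field(
        default_factory=lambda: {
            "queen_biased": purifying_regime(),
            "worker_biased": purifying_regime(),
            "unbiased": purifying_regime(),
        }
    )
    codons_per_gene: int = 400
    intergenic_bp: int = 600
    gc_content: float = 0.37
    mu: float = 3.5e-9
    t_split: int = 600_000          # generations; one generation per year
    poly_density: float = 0.01      # expected segregating sites / bp / species
    sfs_chromosomes: int = 20       # ancestral-frequency grid for the 1/i SFS
    bn_f: float = 0.15              # Balding-Nichols F between populations
    n_diploids_per_pop: int = 8
    missing_rate: float = 0.02
    # expression
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    nb_dispersion: float = 0.1
    true_lfc: float = 3.0
    tissue_lfc_sd: float = 0.5
    depth_log2_sd: float = 0.3
    n_colonies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.poly_density < 0 or not (0 <= self.bn_f < 1):
            raise ValueError("rates must be >= 0 and F in [0,1)")
        if set(self.n_genes_per_class) != set(self.regimes):
            raise ValueError("class labels of n_genes_per_class and regimes must match")


# ---------------------------------------------------------------------------
# reference genome layout


_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTOP, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def _build_genome(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay genes head to tail on one contig, alternating strand."""
    classes = [c for c, n in cfg.n_genes_per_class.items() for _ in range(n)]
    rng.shuffle(classes)
    gene_bp = 3 * cfg.codons_per_gene
    p = cfg.gc_content / 2
    probs = [0.5 - p, p, p, 0.5 - p]  # A C G T
    pieces, genes, cds_strings = [], [], []
    cursor = 1
    for gi, cls in enumerate(classes):
        gap = "".join(rng.choice(list("ACGT"), size=cfg.intergenic_bp, p=probs))
        pieces.append(gap)
        cursor += cfg.intergenic_bp
        strand = "+" if gi % 2 == 0 else "-"
        cds = _random_cds(rng, cfg.codons_per_gene)
        genomic = cds if strand == "+" else revcomp(cds)
        pieces.append(genomic)
        gene = GeneAnnotation(
            gene_id=f"gene{gi:05d}",
            contig="chr1",
            strand=strand,
            cds_segments=[(cursor, cursor + gene_bp - 1)],
            phase=0,
        )
        genes.append(gene)
        cds_strings.append(cds)
        cursor += gene_bp
    pieces.append("".join(rng.choice(list("ACGT"), size=cfg.intergenic_bp, p=probs)))
    seqs = SequenceSet({"chr1": "".join(pieces)})
    return seqs, genes, cds_strings, classes


def _classify_cds_change(cds: str, i: int, alt_t: str) -> str:
    """Generator-side effect call, independent of the analysis classifier."""
    ci = i // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mutated = codon[: i % 3] + alt_t + codon[i % 3 + 1 :]
    aa0 = str(Seq(codon).translate())
    aa1 = str(Seq(mutated).translate())
    if aa0 == aa1:
        return "synonymous"
    if aa1 == "*":
        return "nonsense"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# allele-frequency machinery


def _neutral_sfs_p(rng: np.random.Generator, m: int) -> float:
    """Ancestral derived-allele frequency i/m with P(i) proportional to 1/i."""
    i = np.arange(1, m)
    w = 1.0 / i
    return float(rng.choice(i, p=w / w.sum())) / m


def balding_nichols_freq(rng: np.random.Generator, p: float, f: float) -> float:
    """Population allele frequency under the Balding-Nichols Beta model."""
    if f <= 0:
        return p
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# genotype simulation


@dataclass
class GroundTruth:
    sites: pd.DataFrame   # contig,pos,gene_id,effect,mode,gene_class,regime
    genes: pd.DataFrame   # gene_id,gene_class,regime,true_lfc


def _make_samples(cfg: SimulationConfig):
    samples, species, population = [], [], []
    for sp in SPECIES:
        for pop in POPULATIONS[sp]:
            for k in range(cfg.n_diploids_per_pop):
                samples.append(f"{pop}_{k:02d}")
                species.append(sp)
                population.append(pop)
    return samples, np.array(species, dtype=object), np.array(population, dtype=object)


def simulate_genomes(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Emit (SequenceSet, genes, VariantTable, GroundTruth) under ``cfg``.

    Divergence mode plants fixed interspecies differences (Poisson with mean
    L * 2*mu*t_split per gene plus k_sweeps forced nonsynonymous ones);
    polymorphism mode plants within-species segregating sites with
    Balding-Nichols population frequencies around a neutral-SFS ancestral
    frequency. Nonsynonymous candidates are thinned by the regime's f_del in
    both modes.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    seqs, genes, cds_strings, classes = _build_genome(cfg, rng)
    samples, species_arr, pop_arr = _make_samples(cfg)
    n_samples = len(samples)
    sp_masks = {sp: species_arr == sp for sp in SPECIES}
    pop_masks = {pop: pop_arr == pop for sp in SPECIES for pop in POPULATIONS[sp]}

    contig_seq = seqs["chr1"]
    sites: dict[int, dict] = {}

    def _genomic_alt(gene: GeneAnnotation, cds_i: int, alt_t: str) -> tuple[int, str]:
        start, end = gene.cds_segments[0]
        if gene.strand == "+":
            return start + cds_i, alt_t  # cds index is 0-based
        return end - cds_i, revcomp(alt_t)

    def _add_fixed(pos: int, ref: str, alt: str, meta: dict) -> None:
        if pos in sites:
            return
        derived_sp = SPECIES[int(rng.integers(2))]
        g = np.zeros(n_samples, dtype=np.int8)
        g[sp_masks[derived_sp]] = 2
        sites[pos] = {"ref": ref, "alt": alt, "geno": g,
                      "mode": "divergence", "derived_species": derived_sp, **meta}

    def _add_poly(pos: int, ref: str, alt: str, sp: str, f_bn: float, meta: dict) -> None:
        if pos in sites:
            return
        p_anc = _neutral_sfs_p(rng, cfg.sfs_chromosomes)
        g = np.zeros(n_samples, dtype=np.int8)
        for pop in POPULATIONS[sp]:
            p_pop = balding_nichols_freq(rng, p_anc, f_bn)
            idx = np.flatnonzero(pop_masks[pop])
            g[idx] = rng.binomial(2, p_pop, size=len(idx))
        if g.sum() == 0 or (g[sp_masks[sp]] == 2).all():
            return  # monomorphic after sampling; not a variant record
        sites[pos] = {"ref": ref, "alt": alt, "geno": g,
                      "mode": "polymorphism", "derived_species": sp, **meta}

    def _random_alt(base: str) -> str:
        return rng.choice([b for b in "ACGT" if b != base])

    div_rate = 2 * cfg.mu * cfg.t_split

    for gene, cds, cls in zip(genes, cds_strings, classes):
        reg: Regime = cfg.regimes[cls]
        L = len(cds)
        lo = 3  # spare the start codon
        hi = L - 3  # spare the stop codon
        meta_base = {"gene_id": gene.gene_id, "gene_class": cls, "regime": reg.kind}

        # --- fixed differences
        n_fix = rng.poisson(L * div_rate)
        placed_sweeps = 0
        attempts = 0
        want_extra = reg.k_sweeps
        while n_fix > 0 or placed_sweeps < want_extra:
            attempts += 1
            if attempts > 50 * (n_fix + want_extra + 1):
                break
            i = int(rng.integers(lo, hi))
            alt_t = _random_alt(cds[i])
            effect = _classify_cds_change(cds, i, alt_t)
            if n_fix > 0:
                n_fix -= 1
                if effect in ("nonsynonymous", "nonsense") and rng.random() < reg.f_del:
                    continue
                pos, alt_g = _genomic_alt(gene, i, alt_t)
                _add_fixed(pos, contig_seq[pos - 1], alt_g, {**meta_base, "effect": effect})
            elif placed_sweeps < want_extra:
                if effect != "nonsynonymous":
                    continue
                pos, alt_g = _genomic_alt(gene, i, alt_t)
                _add_fixed(pos, contig_seq[pos - 1], alt_g,
                           {**meta_base, "effect": effect, "sweep": True})
                placed_sweeps += 1

        # --- polymorphism, independently per species
        f_here = reg.f_local if reg.f_local is not None else cfg.bn_f
        for sp in SPECIES:
            n_poly = rng.poisson(L * cfg.poly_density)
            for _ in range(n_poly):
                i = int(rng.integers(lo, hi))
                alt_t = _random_alt(cds[i])
                effect = _classify_cds_change(cds, i, alt_t)
                if effect in ("nonsynonymous", "nonsense") and rng.random() < reg.f_del:
                    continue
                pos, alt_g = _genomic_alt(gene, i, alt_t)
                _add_poly(pos, contig_seq[pos - 1], alt_g, sp, f_here,
                          {**meta_base, "effect": effect})

    # --- intergenic (neutral) variation across the whole contig
    coding = np.zeros(len(contig_seq) + 2, dtype=bool)
    for gene in genes:
        s, e = gene.cds_segments[0]
        coding[s : e + 1] = True
    inter_pos = np.flatnonzero(~coding[1 : len(contig_seq) + 1]) + 1
    inter_meta = {"gene_id": "", "gene_class": "", "regime": "", "effect": "noncoding"}
    for pos in inter_pos[rng.random(len(inter_pos)) < div_rate]:
        ref = contig_seq[pos - 1]
        _add_fixed(int(pos), ref, _random_alt(ref), dict(inter_meta))
    for sp in SPECIES:
        for pos in inter_pos[rng.random(len(inter_pos)) < cfg.poly_density]:
            ref = contig_seq[pos - 1]
            _add_poly(int(pos), ref, _random_alt(ref), sp, cfg.bn_f, dict(inter_meta))

    # --- assemble, in position order, with missingness
    positions = np.array(sorted(sites), dtype=np.int64)
    geno = np.stack([sites[p]["geno"] for p in positions]) if len(positions) else \
        np.empty((0, n_samples), np.int8)
    if cfg.missing_rate > 0 and geno.size:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(miss, np.int8(MISSING), geno)
    vt = VariantTable(
        contig=np.array(["chr1"] * len(positions), dtype=object),
        pos=positions,
        ref=np.array([sites[p]["ref"] for p in positions], dtype=object),
        alt=np.array([sites[p]["alt"] for p in positions], dtype=object),
        genotypes=geno,
        samples=samples,
        species=species_arr,
        population=pop_arr,
    )
    site_truth = pd.DataFrame(
        [
            {
                "contig": "chr1",
                "pos": int(p),
                "gene_id": sites[p]["gene_id"],
                "gene_class": sites[p]["gene_class"],
                "regime": sites[p]["regime"],
                "effect": sites[p]["effect"],
                "mode": sites[p]["mode"],
                "derived_species": sites[p].get("derived_species", ""),
            }
            for p in positions
        ]
    )
    lfc_sign = {"queen_biased": 1.0, "worker_biased": -1.0, "unbiased": 0.0}
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_class": classes,
            "regime": [cfg.regimes[c].kind for c in classes],
            "true_lfc": [lfc_sign.get(c, 0.0) * cfg.true_lfc for c in classes],
        }
    )
    return seqs, genes, vt, GroundTruth(sites=site_truth, genes=gene_truth)


# ---------------------------------------------------------------------------
# neutral-SFS panel (estimator calibration)


def simulate_neutral_sfs_panel(
    n_diploids: int = 10,
    contig_length: int = 2_000_000,
    s_density: float = 0.005,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> VariantTable:
    """Single-population panel whose site frequencies follow the neutral SFS.

    Each segregating site carries exactly i derived copies among the 2n
    sampled chromosomes with P(i) proportional to 1/i, assigned to random
    chromosomes; the standard neutrality statistics are centred on their
    null values by construction.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    m = 2 * n_diploids
    n_sites = rng.poisson(contig_length * s_density)
    pos = np.sort(rng.choice(np.arange(1, contig_length + 1), size=n_sites, replace=False))
    i_vals = np.arange(1, m)
    w = 1.0 / i_vals
    counts = rng.choice(i_vals, size=n_sites, p=w / w.sum())
    geno = np.zeros((n_sites, n_diploids), dtype=np.int8)
    for s in range(n_sites):
        chroms = rng.choice(m, size=counts[s], replace=False)
        for c in chroms:
            geno[s, c // 2] += 1
    samples = [f"ind{k:02d}" for k in range(n_diploids)]
    return VariantTable(
        contig=np.array(["chr1"] * n_sites, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        genotypes=geno,
        samples=samples,
        species=np.array(["carbonaria"] * n_diploids, dtype=object),
        population=np.array(["pop1"] * n_diploids, dtype=object),
    )


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Caste x tissue x colony negative-binomial counts.

    Queen-biased genes are expressed 2^true_lfc higher in queens than in
    both worker groups (worker-biased genes the reverse); males sit at
    baseline; forager and in-nest workers share means. A per-gene tissue
    effect and per-sample depth factor are layered on top.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    gene_ids = truth.genes.gene_id.to_numpy()
    cls = truth.genes.gene_class.to_numpy()
    n_genes = len(gene_ids)
    if baseline is None:
        base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes)
    else:
        base = np.asarray(baseline, dtype=float)
    if (base <= 0).any():
        raise ValueError("non-positive baseline expression")
    tissue_eff = rng.normal(0.0, cfg.tissue_lfc_sd, size=n_genes)
    half = cfg.true_lfc / 2.0
    caste_log2 = {caste: np.zeros(n_genes) for caste in CASTES}
    caste_log2["queen"][cls == "queen_biased"] += half
    for w in ("forager", "innest_worker"):
        caste_log2[w][cls == "queen_biased"] -= half
        caste_log2[w][cls == "worker_biased"] += half
    caste_log2["queen"][cls == "worker_biased"] -= half

    cols, meta_rows = [], []
    data = {}
    for caste in CASTES:
        for colony in range(1, cfg.n_colonies + 1):
            for tissue in TISSUES:
                name = f"{caste}_{colony}_{tissue}"
                depth = 2.0 ** rng.normal(0.0, cfg.depth_log2_sd)
                mu = base * 2.0 ** caste_log2[caste] * 2.0 ** (tissue_eff * (tissue == "abdomen")) * depth
                if cfg.nb_dispersion <= 1e-8:
                    counts = rng.poisson(mu)
                else:
                    r = 1.0 / cfg.nb_dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                data[name] = counts
                cols.append(name)
                meta_rows.append({"sample": name, "caste": caste, "tissue": tissue,
                                  "colony": f"colony{colony}"})
    counts_df = pd.DataFrame(data, index=gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(counts=counts_df, meta=meta)


# ---------------------------------------------------------------------------
# scenario presets (the study conditions exercised by the analysis scripts)


def neutral_scenario(n_per_class: int = 300, seed: int = 0) -> SimulationConfig:
    """No regime differences between classes: every class neutral."""
    return SimulationConfig(
        n_genes_per_class={c: n_per_class for c in ("queen_biased", "worker_biased", "unbiased")},
        regimes={c: neutral_regime() for c in ("queen_biased", "worker_biased", "unbiased")},
        seed=seed,
    )


def relaxed_worker_scenario(n_per_class: int = 300, seed: int = 0) -> SimulationConfig:
    """Worker-biased genes under relaxed purifying selection (f_del 0.8 -> 0.1)."""
    return SimulationConfig(
        n_genes_per_class={c: n_per_class for c in ("queen_biased", "worker_biased", "unbiased")},
        regimes={
            "queen_biased": purifying_regime(0.8),
            "worker_biased": relaxed_regime(0.1),
            "unbiased": purifying_regime(0.8),
        },
        seed=seed,
    )


def adapted_worker_scenario(n_per_class: int = 300, seed: int = 0) -> SimulationConfig:
    """Worker-biased genes under recurrent positive selection (3 sweeps/gene)."""
    return SimulationConfig(
        n_genes_per_class={c: n_per_class for c in ("queen_biased", "worker_biased", "unbiased")},
        regimes={
            "queen_biased": neutral_regime(),
            "worker_biased": positive_regime(k_sweeps=3, f_local=0.45),
            "unbiased": neutral_regime(),
        },
        seed=seed,
    )
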