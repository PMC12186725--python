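"""Within- and between-population genomic statistics on a VariantTable.

pi and dxy follow the missing-data-aware convention: each site contributes
the fraction of differing haplotype pairs among pairs where both members are
called, and the window value divides the summed per-site fractions by the
number of compared sites (the full window span when no callable mask is
given). FST uses the Weir & Cockerham (1984) two-population diploid variance
components; Tajima's D uses the 1989 constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GeneAnnotation, VariantTable


@dataclass
class WindowStat:
    contig: str
    start: int
    end: int  # 1-based inclusive
    n_sites_compared: float
    n_diffs: float
    value: float  # nan when no compared sites


# ---------------------------------------------------------------------------
# SNP filtering


def site_allele_stats(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (called allele count, alt allele count) over a genotype matrix."""
    called = geno != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, geno, 0).sum(axis=1)
    return an, ac


def filter_snps(vt: VariantTable, maf_min: float = 0.05, min_called_alleles: int = 50) -> VariantTable:
    """Completeness (AN >= threshold) and minor-allele-frequency (>= maf_min) filters.

    The MAF boundary is inclusive: a site at exactly ``maf_min`` is kept.
    A per-reason removal report is attached to the result.
    """
    an, ac = site_allele_stats(vt.genotypes)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    maf = np.minimum(af, 1 - af)
    an_ok = an >= min_called_alleles
    maf_ok = maf >= maf_min
    keep = an_ok & maf_ok
    out = vt.take_sites(keep)
    out.filter_report = {
        "an": int((~an_ok).sum()),
        "maf": int((an_ok & ~maf_ok).sum()),
        "kept": int(keep.sum()),
    }
    return out


# ---------------------------------------------------------------------------
# LD pruning


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(vt: VariantTable, r2_max: float = 0.8, window_bp: int = 500_000) -> VariantTable:
    """Greedy left-to-right pruning: a site is dropped when its genotype
    correlation r^2 with any previously kept site within ``window_bp`` on the
    same contig exceeds ``r2_max``. Deterministic in position order."""
    keep = np.zeros(vt.n_sites, dtype=bool)
    order = np.lexsort((vt.pos, vt.contig.astype(str)))
    kept_by_contig: dict[str, list[int]] = {}
    for i in order:
        ctg = vt.contig[i]
        kept = kept_by_contig.setdefault(ctg, [])
        ok = True
        for j in reversed(kept):
            if vt.pos[i] - vt.pos[j] > window_bp:
                break
            if _r2(vt.genotypes[i], vt.genotypes[j]) > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
            keep[i] = True
    return vt.take_sites(keep)


# ---------------------------------------------------------------------------
# pi / dxy


def _pi_site_fractions(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (differing-pair fraction, comparable flag) within one group.

    Haplotype counts derive from dosages: n called haplotypes, d alt copies;
    differing pairs = d(n-d) of n(n-1)/2 total.
    """
    called = geno != MISSING
    n = 2 * called.sum(axis=1)
    d = np.where(called, geno, 0).sum(axis=1)
    pairs = n * (n - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pairs > 0, d * (n - d) / np.maximum(pairs, 1), np.nan)
    return frac, n >= 2


def _dxy_site_fractions(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ca, cb = ga != MISSING, gb != MISSING
    na, nb = 2 * ca.sum(axis=1), 2 * cb.sum(axis=1)
    da = np.where(ca, ga, 0).sum(axis=1)
    db = np.where(cb, gb, 0).sum(axis=1)
    cross = na * nb
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cross > 0, (da * (nb - db) + db * (na - da)) / np.maximum(cross, 1), np.nan)
    return frac, (na >= 1) & (nb >= 1)


def _windows(vt: VariantTable, window_bp: int, contig_lengths: dict[str, int] | None):
    for ctg in dict.fromkeys(vt.contig):
        in_ctg = vt.contig == ctg
        length = (contig_lengths or {}).get(ctg, int(vt.pos[in_ctg].max()))
        for start in range(1, length + 1, window_bp):
            end = min(start + window_bp - 1, length)
            yield ctg, start, end, in_ctg & (vt.pos >= start) & (vt.pos <= end)


def _aggregate_windows(vt, frac, comparable, window_bp, contig_lengths, callable_mask):
    out = []
    for ctg, start, end, m in _windows(vt, window_bp, contig_lengths):
        idx = np.flatnonzero(m)
        good = idx[comparable[idx]]
        diffs = float(np.nansum(frac[good]))
        if callable_mask is not None:
            span_sites = int(callable_mask.get(ctg, np.zeros(0, bool))[start - 1 : end].sum())
            n_comp = span_sites - (len(idx) - len(good))
        else:
            n_comp = (end - start + 1) - (len(idx) - len(good))
        value = diffs / n_comp if n_comp > 0 else np.nan
        out.append(WindowStat(ctg, start, end, n_comp, diffs, value))
    return out


def pi_windows(
    vt: VariantTable,
    population: str | None = None,
    window_bp: int = 10_000,
    callable_mask: dict[str, np.ndarray] | None = None,
    contig_lengths: dict[str, int] | None = None,
    species: str | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity for one population (or species).

    Without a callable mask every non-variant position in the window is
    assumed callable and invariant; variant sites with fewer than two called
    haplotypes are excluded from the denominator.
    """
    m = vt.sample_mask(species=species, population=population)
    if not m.any():
        raise ValueError(f"no samples for population={population!r} species={species!r}")
    frac, comp = _pi_site_fractions(vt.genotypes[:, m])
    return _aggregate_windows(vt, frac, comp, window_bp, contig_lengths, callable_mask)


def dxy_windows(
    vt: VariantTable,
    group_a: dict,
    group_b: dict,
    window_bp: int = 10_000,
    callable_mask: dict[str, np.ndarray] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed absolute divergence between two groups.

    ``group_a``/``group_b`` are keyword dicts for :meth:`VariantTable.sample_mask`,
    e.g. ``{"species": "carbonaria"}`` or ``{"population": "north"}``.
    """
    ma, mb = vt.sample_mask(**group_a), vt.sample_mask(**group_b)
    if not ma.any() or not mb.any():
        raise ValueError("empty group in dxy")
    frac, comp = _dxy_site_fractions(vt.genotypes[:, ma], vt.genotypes[:, mb])
    return _aggregate_windows(vt, frac, comp, window_bp, contig_lengths, callable_mask)


def overall_mean(windows: list[WindowStat]) -> float:
    """Unweighted mean of window values (the headline aggregation); nan-safe."""
    vals = np.array([w.value for w in windows], dtype=float)
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan


def site_weighted_mean(windows: list[WindowStat]) -> float:
    num = sum(w.n_diffs for w in windows if w.n_sites_compared > 0)
    den = sum(w.n_sites_compared for w in windows)
    return num / den if den > 0 else np.nan


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


def wc_components(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (a, b, c) variance components for two diploid populations.

    Direct transcription of the two-allele, r=2 estimator with observed
    heterozygote frequencies; sites where either population has fewer than
    one called genotype yield nan components.
    """
    r = 2.0
    ca, cb = ga != MISSING, gb != MISSING
    n1 = ca.sum(axis=1).astype(float)
    n2 = cb.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ca, ga, 0).sum(axis=1) / (2 * np.maximum(n1, 1))
        p2 = np.where(cb, gb, 0).sum(axis=1) / (2 * np.maximum(n2, 1))
        h1 = np.where(ca, ga == 1, 0).sum(axis=1) / np.maximum(n1, 1)
        h2 = np.where(cb, gb == 1, 0).sum(axis=1) / np.maximum(n2, 1)
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def weir_cockerham_fst(
    vt: VariantTable, group_a: dict, group_b: dict
) -> tuple[pd.DataFrame, float, float]:
    """Per-SNP theta plus unweighted and weighted genome means.

    unweighted = mean of theta over sites with a+b+c != 0;
    weighted = sum(a) / sum(a+b+c). Negative theta values are retained.
    """
    ma, mb = vt.sample_mask(**group_a), vt.sample_mask(**group_b)
    ga, gb = vt.genotypes[:, ma], vt.genotypes[:, mb]
    if ((ga != MISSING).sum(axis=1) >= 2).sum() == 0 or ((gb != MISSING).sum(axis=1) >= 2).sum() == 0:
        raise ValueError("a group lacks >=2 genotyped individuals at every site")
    a, b, c = wc_components(ga, gb)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    df = pd.DataFrame(
        {"contig": vt.contig, "pos": vt.pos, "a": a, "b": b, "c": c, "theta": theta}
    )
    ok = np.isfinite(theta)
    mean_unweighted = float(np.mean(theta[ok])) if ok.any() else np.nan
    fin = np.isfinite(denom)
    tot = denom[fin].sum()
    mean_weighted = float(a[fin].sum() / tot) if tot != 0 else np.nan
    return df, mean_unweighted, mean_weighted


# ---------------------------------------------------------------------------
# F_IS, Tajima's D, ROH


def fis_per_individual(vt: VariantTable, population: str) -> pd.Series:
    """Individual inbreeding coefficient F = (O_hom - E_hom)/(N - E_hom).

    Expected homozygosity uses population allele frequencies with the
    small-sample correction 1 - 2p(1-p) * 2n/(2n-1) at each of the
    individual's called sites.
    """
    m = vt.sample_mask(population=population)
    if not m.any():
        raise ValueError(f"population {population!r} absent")
    g = vt.genotypes[:, m]
    names = [s for s, keep in zip(vt.samples, m) if keep]
    an, ac = site_allele_stats(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        e_hom_site = 1 - 2 * p * (1 - p) * an / np.maximum(an - 1, 1)
    out = {}
    for j, name in enumerate(names):
        called = g[:, j] != MISSING
        usable = called & (an > 1)
        n_sites = int(usable.sum())
        if n_sites == 0:
            out[name] = np.nan
            continue
        o_hom = int(((g[:, j] == 0) | (g[:, j] == 2))[usable].sum())
        e_hom = float(e_hom_site[usable].sum())
        denom = n_sites - e_hom
        out[name] = (o_hom - e_hom) / denom if denom != 0 else np.nan
    return pd.Series(out, name="fis")


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) a1..e2 for n sampled haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    vt: VariantTable,
    population: str | None = None,
    window_bp: int = 10_000,
    contig_lengths: dict[str, int] | None = None,
    species: str | None = None,
) -> list[WindowStat]:
    """Windowed Tajima's D; undefined (nan) where S = 0 or n < 4.

    n is the modal number of called haplotypes over the window's segregating
    sites; sites with fewer calls still count toward S.
    """
    m = vt.sample_mask(species=species, population=population)
    g = vt.genotypes[:, m]
    called = g != MISSING
    nhap = 2 * called.sum(axis=1)
    d = np.where(called, g, 0).sum(axis=1)
    seg = (d > 0) & (d < nhap)
    out = []
    for ctg, start, end, win in _windows(vt, window_bp, contig_lengths):
        idx = np.flatnonzero(win & seg)
        S = len(idx)
        if S == 0:
            out.append(WindowStat(ctg, start, end, 0, 0.0, np.nan))
            continue
        vals, counts = np.unique(nhap[idx], return_counts=True)
        n = int(vals[np.argmax(counts)])
        if n < 4:
            out.append(WindowStat(ctg, start, end, S, 0.0, np.nan))
            continue
        k = float(np.sum(d[idx] * (nhap[idx] - d[idx]) / (nhap[idx] * (nhap[idx] - 1) / 2)))
        c = tajima_constants(n)
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        D = (k - S / c["a1"]) / np.sqrt(var) if var > 0 else np.nan
        out.append(WindowStat(ctg, start, end, S, k, float(D)))
    return out


def roh_detect(
    vt: VariantTable,
    sample: str,
    min_snps: int = 50,
    max_het: int = 1,
    min_bp: int = 100_000,
) -> tuple[pd.DataFrame, float]:
    """Runs of homozygosity from a sliding window of called sites.

    Every window of ``min_snps`` consecutive called sites with at most
    ``max_het`` heterozygous calls seeds a run; overlapping seeds merge, and
    merged intervals shorter than ``min_bp`` are dropped. f(ROH) is the
    summed run length over the total assayed span (first to last called
    site, per contig).
    """
    j = vt.samples.index(sample)
    rows, assayed, covered = [], 0, 0
    for ctg in dict.fromkeys(vt.contig):
        m = (vt.contig == ctg) & (vt.genotypes[:, j] != MISSING)
        pos = vt.pos[m]
        g = vt.genotypes[m, j]
        if len(pos) == 0:
            continue
        assayed += int(pos[-1] - pos[0] + 1)
        if len(pos) < min_snps:
            continue
        het = (g == 1).astype(int)
        chet = np.concatenate([[0], np.cumsum(het)])
        seeds = []
        for k in range(len(pos) - min_snps + 1):
            if chet[k + min_snps] - chet[k] <= max_het:
                seeds.append((int(pos[k]), int(pos[k + min_snps - 1])))
        merged = []
        for s, e in seeds:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s + 1 >= min_bp:
                rows.append({"contig": ctg, "start": s, "end": e, "length": e - s + 1})
                covered += e - s + 1
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "length"])
    froh = covered / assayed if assayed > 0 else np.nan
    return df, float(froh)


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(vt: VariantTable, n_components: int = 10):
    """Genotype PCA with p(1-p) scaling; missing dosages imputed to site mean.

    Returns (coordinates DataFrame indexed by sample, explained-variance array).
    """
    g = vt.genotypes.astype(float).T  # samples x sites
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    p = mean / 2
    scale = np.sqrt(p * (1 - p))
    keep = np.isfinite(scale) & (scale > 0)
    g, mean, scale = g[:, keep], mean[keep], scale[keep]
    x = (g - mean) / scale
    x[~np.isfinite(x)] = 0.0  # mean imputation after centering
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    evals = s**2 / (n - 1)
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k], index=vt.samples, columns=[f"PC{i+1}" for i in range(k)]
    )
    return coords, evals


# ---------------------------------------------------------------------------
# FST x annotation


def annotate_snp_category(
    contigs: np.ndarray, pos: np.ndarray, genes: list[GeneAnnotation]
) -> np.ndarray:
    """Assign each SNP one category with precedence CDS > gene span (UTR/intron)
    > intergenic; 1-based inclusive boundaries."""
    cds: dict[str, list[tuple[int, int]]] = {}
    span: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for s, e in g.cds_segments:
            cds.setdefault(g.contig, []).append((s, e))
        span.setdefault(g.contig, []).append(g.span)
    out = np.full(len(pos), "intergenic", dtype=object)

    def _hit(table, ctg, p):
        return any(s <= p <= e for s, e in table.get(ctg, ()))

    for i in range(len(pos)):
        if _hit(cds, contigs[i], pos[i]):
            out[i] = "cds"
        elif _hit(span, contigs[i], pos[i]):
            out[i] = "utr_intron"
    return out


def fst_bins_cds_fraction(
    site_fst: pd.DataFrame, genes: list[GeneAnnotation], bin_width: float = 0.1
) -> tuple[pd.DataFrame, float, float]:
    """Per-FST-bin annotation-category fractions and the Pearson correlation
    between bin midpoint and CDS fraction. Negative theta is clamped into the
    first bin; empty bins are excluded from the correlation."""
    df = site_fst.dropna(subset=["theta"]).copy()
    df["category"] = annotate_snp_category(df.contig.to_numpy(), df.pos.to_numpy(), genes)
    clamped = np.clip(df.theta.to_numpy(), 0.0, 1.0)
    nbins = int(round(1.0 / bin_width))
    idx = np.minimum((clamped / bin_width).astype(int), nbins - 1)
    rows = []
    for b in range(nbins):
        sub = df[idx == b]
        n = len(sub)
        row = {"bin_lo": b * bin_width, "bin_mid": (b + 0.5) * bin_width, "n_snps": n}
        for cat in ("cds", "utr_intron", "intergenic"):
            row[f"fraction_{cat}"] = (sub.category == cat).mean() if n else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    occ = table.dropna(subset=["fraction_cds"])
    if len(occ) >= 2 and occ.fraction_cds.nunique() > 1:
        r, p = stats.pearsonr(occ.bin_mid, occ.fraction_cds)
    else:
        r, p = np.nan, np.nan
    return table, float(r), float(p)


def flag_divergent_genes(
    site_fst: pd.DataFrame,
    genes: list[GeneAnnotation],
    fst_high: float = 0.90,
    min_cds_snps: int = 3,
) -> pd.DataFrame:
    """Genes with >= min_cds_snps CDS SNPs at theta strictly above fst_high."""
    hi = site_fst[site_fst.theta > fst_high]
    rows = []
    for g in genes:
        in_gene = hi[hi.contig == g.contig]
        n = sum(
            any(s <= p <= e for s, e in g.cds_segments) for p in in_gene.pos
        )
        if n >= min_cds_snps:
            rows.append({"gene_id": g.gene_id, "n_high_fst_cds_snps": n})
    return pd.DataFrame(rows, columns=["gene_id", "n_high_fst_cds_snps"])


def fixed_snp_cds_intersect(
    site_fst: pd.DataFrame, genes: list[GeneAnnotation], threshold: float = 0.95
) -> pd.DataFrame:
    """SNPs with theta strictly above ``threshold`` annotated with the CDS gene
    they fall in (empty gene_id when non-coding)."""
    hi = site_fst[site_fst.theta > threshold].copy()
    gene_ids = []
    for ctg, p in zip(hi.contig, hi.pos):
        hit = ""
        for g in genes:
            if g.contig == ctg and any(s <= p <= e for s, e in g.cds_segments):
                hit = g.gene_id
                break
        gene_ids.append(hit)
    hi["gene_id"] = gene_ids
    return hi
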