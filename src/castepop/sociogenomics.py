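"""Combine caste classes with per-gene genomic statistics and decide between
the Relaxed Constraint and Adapted Worker hypotheses.

Relaxed Constraint: indirect selection on worker-expressed genes weakens
purifying selection, predicting elevated worker pi, dxy and NI, dN/dS
elevated yet below one, and no FST elevation. Adapted Worker: recurrent
positive selection on worker genes, predicting positive and elevated DoS,
dN/dS above one, and elevated FST without elevated dxy. The verdict is a
deterministic function of the signed, BH-significant worker-vs-queen
contrasts; a per-prediction ledger is always returned so other decision
rules can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MISSING, GeneAnnotation, VariantTable
from .popgen_stats import _dxy_site_fractions, _pi_site_fractions, wc_components

CLASSES = ("queen_biased", "worker_biased", "unbiased")


# ---------------------------------------------------------------------------
# per-gene statistics


def per_gene_statistics(
    vt: VariantTable,
    genes: list[GeneAnnotation],
    focal_species: str,
    sister_species: str,
    mk: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """pi, dxy and weighted FST over each gene's genomic span, merged with
    MK statistics, gene features and caste classes when supplied.

    pi is computed within the focal species; dxy between the two species;
    FST is the weighted Weir-Cockerham mean over the span's SNPs between the
    species. Genes without compared sites get nan and a flag.
    """
    mf = vt.sample_mask(species=focal_species)
    ms = vt.sample_mask(species=sister_species)
    pi_frac, pi_ok = _pi_site_fractions(vt.genotypes[:, mf])
    dxy_frac, dxy_ok = _dxy_site_fractions(vt.genotypes[:, mf], vt.genotypes[:, ms])
    a, b, c = wc_components(vt.genotypes[:, mf], vt.genotypes[:, ms])
    denom = a + b + c

    by_contig: dict[str, np.ndarray] = {}
    for ctg in dict.fromkeys(vt.contig):
        by_contig[ctg] = np.flatnonzero(vt.contig == ctg)

    rows = []
    for g in genes:
        lo, hi = g.span
        span = hi - lo + 1
        idx = by_contig.get(g.contig, np.empty(0, int))
        sub = idx[(vt.pos[idx] >= lo) & (vt.pos[idx] <= hi)]
        flags = []

        def span_value(frac, ok):
            good = sub[ok[sub]]
            n_comp = span - (len(sub) - len(good))
            return (float(np.nansum(frac[good])) / n_comp if n_comp > 0 else np.nan)

        pi = span_value(pi_frac, pi_ok)
        dxy = span_value(dxy_frac, dxy_ok)
        fin = sub[np.isfinite(denom[sub])]
        tot = denom[fin].sum() if len(fin) else 0.0
        if len(fin) and tot != 0:
            fst = float(a[fin].sum() / tot)
        else:
            fst = np.nan
            flags.append("fst_undefined")
        if len(sub) == 0:
            flags.append("no_snps")
        rows.append(
            {"gene_id": g.gene_id, "pi": pi, "dxy": dxy, "fst": fst,
             "n_snps": len(sub), "flags": ";".join(flags)}
        )
    table = pd.DataFrame(rows)
    if mk is not None:
        table = table.merge(mk.drop(columns=["flags"], errors="ignore"), on="gene_id", how="left")
    if features is not None:
        table = table.merge(features, on="gene_id", how="left")
    if classes is not None:
        cls = classes.rename("gene_class")
        table = table.merge(cls, left_on="gene_id", right_index=True, how="left")
        table["gene_class"] = table.gene_class.fillna("unbiased")
    return table


# ---------------------------------------------------------------------------
# class contrasts


def contrast_by_class(
    table: pd.DataFrame, metric: str, alpha: float = 0.05, min_n: int = 3
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of ``metric`` between caste
    classes, BH-corrected across the metric's three contrasts.

    The exact null is used when the combined sample size is <= 30, else the
    normal approximation with tie correction. ``direction`` is the sign of
    (median of the first class - median of the second).
    """
    vals = {
        c: table.loc[table.gene_class == c, metric].dropna().to_numpy()
        for c in CLASSES
    }
    rows = []
    for ca, cb in combinations(CLASSES, 2):
        x, y = vals[ca], vals[cb]
        if len(x) < min_n or len(y) < min_n:
            rows.append({"metric": metric, "class_a": ca, "class_b": cb, "n_a": len(x),
                         "n_b": len(y), "stat": np.nan, "p": np.nan, "direction": 0})
            continue
        method = "exact" if len(x) + len(y) <= 30 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        direction = int(np.sign(np.median(x) - np.median(y)))
        rows.append({"metric": metric, "class_a": ca, "class_b": cb, "n_a": len(x),
                     "n_b": len(y), "stat": float(res.statistic), "p": float(res.pvalue),
                     "direction": direction})
    df = pd.DataFrame(rows)
    ok = df.p.notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = multipletests(df.p[ok], method="fdr_bh")[1]
    df["significant"] = ok & (df.q < alpha)
    return df


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2 and 2x3 by enumeration)


def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact conditional test for a 2 x C contingency table.

    Enumerates all tables with the observed margins; the p-value sums the
    probabilities of tables no more probable than the observed one
    (two-sided, probability ordering). C of 2 or 3 supported.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2 or table.shape[1] not in (2, 3):
        raise ValueError("2x2 or 2x3 table required")
    if (table < 0).any():
        raise ValueError("negative cell")
    col = table.sum(axis=0)
    r1 = int(table.sum(axis=1)[0])
    n = int(table.sum())
    if r1 == 0 or r1 == n or (col == 0).any():
        return np.nan

    def log_prob(row) -> float:
        return sum(_log_choose(col[j], row[j]) for j in range(len(col))) - _log_choose(n, r1)

    obs = log_prob(table[0])
    total = 0.0
    eps = 1e-9
    if table.shape[1] == 2:
        lo = max(0, r1 - col[1])
        hi = min(r1, col[0])
        for a in range(lo, hi + 1):
            lp = log_prob((a, r1 - a))
            if lp <= obs + eps:
                total += np.exp(lp)
    else:
        for a in range(0, min(r1, col[0]) + 1):
            rem = r1 - a
            lo = max(0, rem - col[2])
            hi = min(rem, col[1])
            for b in range(lo, hi + 1):
                lp = log_prob((a, b, rem - b))
                if lp <= obs + eps:
                    total += np.exp(lp)
    return float(min(total, 1.0))


def phylostratum_contingency(
    table: pd.DataFrame, stratum_predicate, classes=CLASSES
) -> tuple[float, pd.Series]:
    """Fisher's exact test of a phylostratum predicate across caste classes.

    ``stratum_predicate`` maps a phylostratum label to bool (e.g. 'ancient':
    common ancestor Opisthokonta or earlier). Returns (p, per-class
    proportion satisfying the predicate).
    """
    sub = table.dropna(subset=["phylostratum"])
    counts = []
    props = {}
    for c in classes:
        labels = sub.loc[sub.gene_class == c, "phylostratum"]
        hit = labels.map(stratum_predicate).astype(bool)
        counts.append([int(hit.sum()), int((~hit).sum())])
        props[c] = float(hit.mean()) if len(hit) else np.nan
    mat = np.array(counts).T  # 2 x n_classes
    if (mat.sum(axis=0) == 0).any():
        return np.nan, pd.Series(props)
    p = fisher_exact_2xc(mat)
    return p, pd.Series(props)


def gc_diversity_correlation(table: pd.DataFrame) -> tuple[float, float, int]:
    """Spearman correlation (midrank ties, t-approximation p) between gene GC%
    and nucleotide diversity."""
    sub = table.dropna(subset=["gc_percent", "pi"])
    if len(sub) < 3:
        return np.nan, np.nan, len(sub)
    rho, p = stats.spearmanr(sub.gc_percent, sub.pi)
    return float(rho), float(p), len(sub)


# ---------------------------------------------------------------------------
# divergence dating


def divergence_time(dxy: float, mu: float) -> float:
    """Divergence time in years: T = dxy / (2 mu), one generation per year."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if dxy < 0:
        raise ValueError("dxy must be non-negative")
    return dxy / (2.0 * mu)


def divergence_range(dxy: float, mu_low: float, mu_high: float) -> tuple[float, float]:
    """(younger, older) divergence estimates in Ma, rounded to 2 decimals:
    the high mutation rate gives the younger bound."""
    if mu_high < mu_low:
        raise ValueError("mu_high < mu_low")
    young = divergence_time(dxy, mu_high) / 1e6
    old = divergence_time(dxy, mu_low) / 1e6
    return round(young, 2), round(old, 2)


# ---------------------------------------------------------------------------
# hypothesis verdict


@dataclass
class ContrastSummary:
    """Worker-vs-queen evidence for one metric: BH-corrected p, the direction
    (+1 when the worker median exceeds the queen median), and the
    worker-class median."""

    metric: str
    q: float
    direction: int
    worker_median: float = np.nan

    @property
    def sig_higher(self) -> bool:
        return bool(np.isfinite(self.q) and self.q < 0.05 and self.direction > 0)

    @property
    def sig_lower(self) -> bool:
        return bool(np.isfinite(self.q) and self.q < 0.05 and self.direction < 0)


@dataclass
class Verdict:
    verdict: str
    relaxed_tally: int
    adapted_tally: int
    ledger: pd.DataFrame = field(repr=False, default=None)


def summarize_worker_queen(
    table: pd.DataFrame, contrasts: dict[str, pd.DataFrame]
) -> dict[str, ContrastSummary]:
    """Extract the worker-vs-queen row of each metric's contrast table."""
    out = {}
    for metric, df in contrasts.items():
        row = df[
            (df.class_a == "queen_biased") & (df.class_b == "worker_biased")
        ].iloc[0]
        worker_vals = table.loc[table.gene_class == "worker_biased", metric].dropna()
        out[metric] = ContrastSummary(
            metric=metric,
            q=float(row.q) if np.isfinite(row.q) else np.nan,
            direction=-int(row.direction),  # flip: + means worker higher
            worker_median=float(worker_vals.median()) if len(worker_vals) else np.nan,
        )
    return out


def hypothesis_verdict(summaries: dict[str, ContrastSummary]) -> Verdict:
    """Score each hypothesis's predictions and emit the verdict.

    Each prediction scores +1 when its significant pattern matches, -1 when
    the significant pattern is opposite, 0 when non-significant or
    ambiguous (e.g. FST elevated but dxy elevated too, which neither
    confirms nor cleanly contradicts the Adapted Worker FST prediction).
    relaxed_supported / adapted_supported require a tally >= +2 with the
    rival tally <= 0; both >= +2 is 'mixed'; anything else 'inconclusive'.
    """

    def get(metric) -> ContrastSummary:
        return summaries.get(metric, ContrastSummary(metric, np.nan, 0))

    rows = []

    def score(hyp, name, matched, contradicted) -> int:
        s = 1 if matched else (-1 if contradicted else 0)
        rows.append({"hypothesis": hyp, "prediction": name, "score": s})
        return s

    pi, dxy, fst = get("pi"), get("dxy"), get("fst")
    ni, dos, dnds = get("NI"), get("DoS"), get("dNdS")

    relaxed = 0
    relaxed += score("relaxed", "worker pi higher", pi.sig_higher, pi.sig_lower)
    relaxed += score("relaxed", "worker dxy higher", dxy.sig_higher, dxy.sig_lower)
    relaxed += score("relaxed", "worker NI higher", ni.sig_higher, ni.sig_lower)
    relaxed += score(
        "relaxed",
        "worker dN/dS elevated, median <= 1",
        dnds.sig_higher and dnds.worker_median <= 1,
        dnds.sig_lower,
    )
    relaxed += score("relaxed", "worker FST not elevated", fst.sig_lower, fst.sig_higher)

    # DoS medians inside the neutral calibration band (+-0.05) are treated as
    # zero: per-gene DoS at sparse counts carries a small density-dependent
    # bias, so only a clearly positive worker median supports adaptation.
    adapted = 0
    adapted += score(
        "adapted",
        "worker DoS higher, median clearly > 0",
        dos.sig_higher and dos.worker_median > 0.05,
        dos.sig_lower,
    )
    adapted += score(
        "adapted",
        "worker FST higher without dxy elevation",
        fst.sig_higher and not dxy.sig_higher,
        fst.sig_lower,
    )
    adapted += score(
        "adapted",
        "worker dN/dS higher, median > 1",
        dnds.sig_higher and dnds.worker_median > 1,
        dnds.sig_lower,
    )

    any_defined = any(np.isfinite(s.q) for s in summaries.values())
    if not any_defined:
        verdict = "inconclusive"
    elif relaxed >= 2 and adapted >= 2:
        verdict = "mixed"
    elif relaxed >= 2 and adapted <= 0:
        verdict = "relaxed_supported"
    elif adapted >= 2 and relaxed <= 0:
        verdict = "adapted_supported"
    else:
        verdict = "inconclusive"
    return Verdict(verdict, relaxed, adapted, pd.DataFrame(rows))


def run_hypothesis_report(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("pi", "dxy", "fst", "NI", "DoS", "dNdS"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, Verdict]:
    """Full contrast table over ``metrics`` plus the verdict."""
    contrasts = {
        m: contrast_by_class(table, m, alpha=alpha) for m in metrics if m in table.columns
    }
    all_rows = pd.concat(contrasts.values(), ignore_index=True)
    summaries = summarize_worker_queen(table, contrasts)
    return all_rows, hypothesis_verdict(summaries)
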