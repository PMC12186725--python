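"""Caste differential expression: filtering, NB GLM Wald tests, bias classes.

The model is a negative-binomial log-link GLM per gene with caste and
tissue terms, median-of-ratios size factors as offsets, and a per-gene
method-of-moments dispersion. The default differential-expression call is a
threshold-aware Wald test of H0: |log2 fold change| <= lfc_threshold,
BH-corrected per contrast; a post-hoc |LFC| filter on the ordinary beta=0
test is available as an alternative mode.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger("castepop")

LN2 = np.log(2.0)


def filter_low_expression(em: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with overall mean >= 1 read/sample and at least one
    caste x tissue group with mean >= 5 reads/sample."""
    counts = em.counts
    overall = counts.mean(axis=1) >= 1
    groups = em.meta.groupby(["caste", "tissue"], observed=True).groups
    any_group = pd.Series(False, index=counts.index)
    for _, samp in groups.items():
        any_group |= counts[list(samp)].mean(axis=1) >= 5
    keep = overall & any_group
    logger.info("expression filter: %d of %d genes kept", int(keep.sum()), len(keep))
    return ExpressionMatrix(counts=counts.loc[keep], meta=em.meta)


def merge_worker_groups(em: ExpressionMatrix) -> ExpressionMatrix:
    """Relabel forager and in-nest workers as a single 'worker' caste."""
    meta = em.meta.copy()
    meta["caste"] = meta.caste.replace({"forager": "worker", "innest_worker": "worker"})
    return ExpressionMatrix(counts=em.counts, meta=meta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization (geometric-mean reference); genes with a
    zero geometric mean are excluded from factor estimation."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean) & (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene usable for size-factor estimation")
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def moments_dispersion(counts: pd.DataFrame, sf: pd.Series, groups: pd.Series,
                       floor: float = 1e-8) -> pd.Series:
    """Per-gene NB dispersion alpha from normalized within-group moments:
    var = mu + alpha mu^2 averaged over design groups, floored at ``floor``."""
    norm = counts / sf
    num = pd.Series(0.0, index=counts.index)
    den = pd.Series(0.0, index=counts.index)
    for _, samp in norm.T.groupby(groups, observed=True).groups.items():
        sub = norm[list(samp)]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (v - m) * (sub.shape[1] - 1)
        den += m.pow(2) * (sub.shape[1] - 1)
    alpha = (num / den.replace(0, np.nan)).fillna(floor)
    return alpha.clip(lower=floor).rename("dispersion")


def _design(meta: pd.DataFrame, reference_caste: str) -> tuple[np.ndarray, list[str]]:
    castes = [c for c in meta.caste.unique() if c != reference_caste]
    cols = ["intercept"] + [f"caste_{c}" for c in castes]
    x = [np.ones(len(meta))] + [(meta.caste == c).to_numpy(float) for c in castes]
    tissues = sorted(meta.tissue.unique())[1:]
    for t in tissues:
        cols.append(f"tissue_{t}")
        x.append((meta.tissue == t).to_numpy(float))
    return np.column_stack(x), cols


def nb_de_test(
    em: ExpressionMatrix,
    contrast: tuple[str, str] = ("queen", "worker"),
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    mode: str = "threshold",
    max_iter: int = 100,
) -> pd.DataFrame:
    """Per-gene Wald test of the caste contrast in a ~caste+tissue NB GLM.

    ``contrast`` = (A, B) tests expression in A relative to B (B is the
    model's reference level); positive lfc means higher in A. ``mode``:
    'threshold' tests H0 |log2FC| <= lfc_threshold; 'posthoc' tests beta=0
    and additionally requires |lfc| > lfc_threshold for a call.
    Non-converged genes are flagged and excluded from calls.
    """
    caste_a, caste_b = contrast
    present = set(em.meta.caste)
    if not {caste_a, caste_b} <= present:
        raise ValueError(f"contrast castes {contrast} not all present in {sorted(present)}")
    x, cols = _design(em.meta, reference_caste=caste_b)
    ci = cols.index(f"caste_{caste_a}")
    sf = size_factors(em.counts)
    disp = moments_dispersion(
        em.counts, sf, em.meta.caste.astype(str) + "/" + em.meta.tissue.astype(str)
    )
    offset = np.log(sf.to_numpy())
    rows = []
    for gene, y in em.counts.iterrows():
        a = float(disp.loc[gene])
        fam = sm.families.NegativeBinomial(alpha=a)
        converged = True
        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y.to_numpy(float), x, family=fam, offset=offset).fit(
                    maxiter=max_iter, tol=1e-8
                )
            converged = bool(getattr(res, "converged", True))
            beta = res.params[ci]
            se = res.bse[ci]
        except Exception:
            converged, beta, se = False, np.nan, np.nan
        lfc = beta / LN2
        se2 = se / LN2
        if not converged or not np.isfinite(lfc) or not np.isfinite(se2) or se2 <= 0:
            rows.append({"gene_id": gene, "lfc": lfc, "se": se2, "wald_p": np.nan,
                         "converged": False})
            continue
        if mode == "threshold":
            z = max(0.0, (abs(lfc) - lfc_threshold) / se2)
        else:
            z = abs(lfc) / se2
        p = 2 * stats.norm.sf(z)
        rows.append({"gene_id": gene, "lfc": lfc, "se": se2, "wald_p": min(p, 1.0),
                     "converged": True})
    df = pd.DataFrame(rows).set_index("gene_id")
    ok = df.converged & df.wald_p.notna()
    q = pd.Series(np.nan, index=df.index)
    if ok.any():
        q[ok] = multipletests(df.wald_p[ok], method="fdr_bh")[1]
    df["q"] = q
    sig = ok & (df.q < alpha)
    if mode == "posthoc":
        sig &= df.lfc.abs() > lfc_threshold
    called = np.where(~sig, "ns", np.where(df.lfc > 0, "up_A", "up_B"))
    df["called"] = called
    df.attrs["contrast"] = contrast
    return df


def classify_caste_bias(de: pd.DataFrame) -> pd.Series:
    """Map the queen-vs-worker DE calls to queen_biased/worker_biased/unbiased."""
    mapping = {"up_A": "queen_biased", "up_B": "worker_biased", "ns": "unbiased"}
    return de.called.map(mapping).rename("gene_class")


def ortholog_overlap_test(set_a: set, set_b: set, universe_size: int) -> tuple[int, float]:
    """One-sided upper-tail hypergeometric test of the overlap of two gene sets.

    Returns (observed overlap, P(X >= overlap)) with
    X ~ Hypergeometric(universe_size, |set_b|, |set_a|).
    """
    k = len(set_a & set_b)
    if k > min(len(set_a), len(set_b)):
        raise ValueError("overlap exceeds set sizes")
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than universe")
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_b), len(set_a)))
    return k, p


def lfc_correlation(
    ortholog_map: dict[str, str], de_a: pd.DataFrame, de_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation of caste LFCs across one-to-one orthologs present in
    both filtered DE tables. Returns (r, p, n)."""
    pairs = [
        (ga, gb)
        for ga, gb in ortholog_map.items()
        if ga in de_a.index and gb in de_b.index
        and np.isfinite(de_a.lfc[ga]) and np.isfinite(de_b.lfc[gb])
    ]
    if len(pairs) < 3:
        return np.nan, np.nan, len(pairs)
    xa = np.array([de_a.lfc[g] for g, _ in pairs])
    xb = np.array([de_b.lfc[g] for _, g in pairs])
    r, p = stats.pearsonr(xa, xb)
    return float(r), float(p), len(pairs)
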