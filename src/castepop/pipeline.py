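"""End-to-end drivers tying the stages together on one dataset.

These functions are what the numbered analysis scripts, the test suite and
the acceptance script all call: simulate (or load) data, classify caste
bias from expression, compute per-gene genomic statistics, and run the
hypothesis contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coding_selection as cs
from . import expression_caste as ec
from . import popgen_stats as pg
from . import sociogenomics as sg
from . import synthetic_data as syn
from .io_formats import GeneAnnotation, SequenceSet, VariantTable

FOCAL, SISTER = "carbonaria", "hockingsi"


@dataclass
class ScenarioResult:
    table: pd.DataFrame          # per-gene statistics with caste classes
    contrasts: pd.DataFrame      # Wilcoxon contrast table over all metrics
    verdict: sg.Verdict
    de: pd.DataFrame             # queen-vs-worker DE results
    class_recovery: float        # fraction of true biased genes recovered
    truth: syn.GroundTruth


def gene_stat_table(
    vt: VariantTable,
    seqs: SequenceSet,
    genes: list[GeneAnnotation],
    classes: pd.Series,
    focal: str = FOCAL,
    sister: str = SISTER,
) -> pd.DataFrame:
    """Per-gene pi/dxy/FST + MK/NG86 statistics + features + caste class."""
    mk = cs.mk_tables_for_genes(vt, seqs, genes, focal, sister)
    feats = pd.DataFrame([cs.gene_features(seqs, g) for g in genes])
    return sg.per_gene_statistics(
        vt, genes, focal, sister, mk=mk, features=feats, classes=classes
    )


def run_scenario(cfg: syn.SimulationConfig, use_true_classes: bool = False) -> ScenarioResult:
    """Simulate one scenario and run the full sociogenomic analysis.

    Caste classes are recovered through the expression stage (filtering,
    worker-group merge, NB GLM queen-vs-worker contrast) unless
    ``use_true_classes`` is set, in which case the generator's labels are
    used directly.
    """
    seqs, genes, vt, truth = syn.simulate_genomes(cfg)
    em = syn.simulate_counts(cfg, truth)
    em = ec.merge_worker_groups(ec.filter_low_expression(em))
    de = ec.nb_de_test(em, ("queen", "worker"))
    if use_true_classes:
        classes = truth.genes.set_index("gene_id").gene_class
    else:
        classes = ec.classify_caste_bias(de)
    true_cls = truth.genes.set_index("gene_id").gene_class
    biased = true_cls[true_cls != "unbiased"]
    recovered = classes.reindex(biased.index).fillna("unbiased")
    recovery = float((recovered == biased).mean()) if len(biased) else np.nan
    table = gene_stat_table(vt, seqs, genes, classes)
    contrasts, verdict = sg.run_hypothesis_report(table)
    return ScenarioResult(table, contrasts, verdict, de, recovery, truth)


def divergence_time_table(
    vt: VariantTable,
    contig_lengths: dict[str, int],
    mu_low: float = 3.4e-9,
    mu_high: float = 3.6e-9,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """dxy and dated divergence for the species pair and the within-species
    population pairs, mirroring the study's comparisons."""
    pairs = [
        ("carbonaria_vs_hockingsi", {"species": FOCAL}, {"species": SISTER}),
        ("carb_north_vs_south", {"population": "carb_north"}, {"population": "carb_south"}),
        ("hock_north_vs_south", {"population": "hock_north"}, {"population": "hock_south"}),
    ]
    rows = []
    for name, a, b in pairs:
        wins = pg.dxy_windows(vt, a, b, window_bp=window_bp, contig_lengths=contig_lengths)
        dxy = pg.overall_mean(wins)
        young, old = sg.divergence_range(dxy, mu_low, mu_high)
        rows.append({"pair": name, "dxy": dxy, "t_young_ma": young, "t_old_ma": old})
    return pd.DataFrame(rows)
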