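import numpy as np
import pandas as pd
import pytest

from castepop import popgen_stats as pg
from castepop import synthetic_data as syn
from castepop.io_formats import MISSING, GeneAnnotation
from conftest import make_variant_table


# ---------------------------------------------------------------------------
# independent oracles


def haplotypes_at_site(dosages):
    """Expand called diploid dosages to a haplotype allele list (0/1)."""
    out = []
    for g in dosages:
        if g == MISSING:
            continue
        out += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
    return out


def brute_pi_window(geno, span):
    """All-pairs haplotype comparison, summed over sites, over compared sites."""
    diffs, excluded = 0.0, 0
    for site in geno:
        hap = haplotypes_at_site(site)
        n = len(hap)
        if n < 2:
            excluded += 1
            continue
        d = sum(
            1 for i in range(n) for j in range(i + 1, n) if hap[i] != hap[j]
        )
        diffs += d / (n * (n - 1) / 2)
    denom = span - excluded
    return diffs / denom if denom > 0 else np.nan


def brute_dxy_window(ga, gb, span):
    diffs, excluded = 0.0, 0
    for sa, sb in zip(ga, gb):
        ha, hb = haplotypes_at_site(sa), haplotypes_at_site(sb)
        if not ha or not hb:
            excluded += 1
            continue
        d = sum(1 for x in ha for y in hb if x != y)
        diffs += d / (len(ha) * len(hb))
    denom = span - excluded
    return diffs / denom if denom > 0 else np.nan


def wc_theta_oracle(ga, gb):
    """Scalar transcription of the Weir & Cockerham (1984) two-population
    diploid estimator, written independently of the vectorized code."""
    a_list = [g for g in ga if g != MISSING]
    b_list = [g for g in gb if g != MISSING]
    n1, n2 = len(a_list), len(b_list)
    if n1 < 1 or n2 < 1 or n1 + n2 <= 2:
        return np.nan
    r = 2
    p1 = sum(a_list) / (2 * n1)
    p2 = sum(b_list) / (2 * n2)
    h1 = sum(1 for g in a_list if g == 1) / n1
    h2 = sum(1 for g in b_list if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c) if (a + b + c) != 0 else np.nan


def brute_ld_prune(positions, geno, r2_max, window_bp):
    """Exhaustive pairwise pruning with the same later-site-removed rule."""
    kept = []
    for i in range(len(positions)):
        drop = False
        for j in kept:
            if positions[i] - positions[j] > window_bp:
                continue
            x, y = geno[i].astype(float), geno[j].astype(float)
            ok = (geno[i] != MISSING) & (geno[j] != MISSING)
            if ok.sum() >= 2 and x[ok].std() > 0 and y[ok].std() > 0:
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                if r * r > r2_max:
                    drop = True
                    break
        if not drop:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# filtering


class TestFilterSnps:
    def test_called_allele_floor(self):
        # 20 diploids, 5 missing -> AN = 30 < 50
        g = [[1] * 15 + [MISSING] * 5]
        vt = make_variant_table(g)
        out = pg.filter_snps(vt, maf_min=0.0, min_called_alleles=50)
        assert out.n_sites == 0 and out.filter_report["an"] == 1

    def test_maf_boundary_inclusive(self):
        # 10 diploids: 1 alt copy -> maf 0.05 kept; 2nd site 0 alt copies via
        # freq 0.04 needs 25 haplotypes, use 1/20=0.05 vs site of maf 0.04: 1 alt in 25 hets
        g1 = [[1] + [0] * 9]  # maf 1/20 = 0.05
        vt = make_variant_table(g1)
        assert pg.filter_snps(vt, maf_min=0.05, min_called_alleles=0).n_sites == 1
        g2 = [[1] + [0] * 11]  # maf 1/24 ~ 0.0417
        vt2 = make_variant_table(g2)
        assert pg.filter_snps(vt2, maf_min=0.05, min_called_alleles=0).n_sites == 0

    def test_report_counts_by_reason(self):
        # 10 sites x 5 diploids: 2 maf failures, 1 an failure, 7 kept
        rows = []
        for _ in range(7):
            rows.append([1, 1, 0, 0, 1])  # af 0.3
        rows.append([0, 0, 0, 0, 1])      # af 0.1, maf 0.1 ok; make failures:
        rows[-1] = [1, 0, 0, 0, 0]        # af 0.1 -> maf 0.1 >= 0.1? use thresholds below
        rows.append([0, 0, 0, 0, 0])      # monomorphic, maf 0 -> fails maf
        rows.append([MISSING, MISSING, MISSING, 0, 1])  # AN 4 -> fails an
        vt = make_variant_table(rows)
        out = pg.filter_snps(vt, maf_min=0.15, min_called_alleles=6)
        assert out.n_sites == 7
        assert out.filter_report == {"an": 1, "maf": 2, "kept": 7}


class TestLdPrune:
    def test_identical_sites_second_removed(self):
        g = [[0, 1, 2, 1], [0, 1, 2, 1]]
        vt = make_variant_table(g)
        out = pg.ld_prune(vt, r2_max=0.8, window_bp=100)
        assert list(out.pos) == [1]

    def test_independent_sites_kept(self):
        g = [[0, 0, 2, 2], [0, 2, 0, 2]]
        vt = make_variant_table(g)
        assert pg.ld_prune(vt, r2_max=0.8, window_bp=100).n_sites == 2

    def test_matches_bruteforce_on_random_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_sites = int(rng.integers(3, 12))
            n_samp = int(rng.integers(4, 9))
            geno = rng.integers(0, 3, size=(n_sites, n_samp)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 400), size=n_sites, replace=False))
            vt = make_variant_table(geno, pos=pos)
            got = pg.ld_prune(vt, r2_max=0.5, window_bp=120)
            want = brute_ld_prune(pos, geno, 0.5, 120)
            assert list(got.pos) == [pos[i] for i in want]


# ---------------------------------------------------------------------------
# pi / dxy


class TestPiDxy:
    def test_pi_single_site_with_invariant_flank(self):
        # 4 haplotypes {A,A,T,T} at one site + 9 invariant callable sites
        vt = make_variant_table([[0, 2]], pos=[1])
        wins = pg.pi_windows(vt, population="pop1", window_bp=10,
                             contig_lengths={"chr1": 10})
        assert wins[0].value == pytest.approx((4 / 6) / 10)

    def test_monomorphic_window_is_zero(self):
        vt = make_variant_table([[0, 0]], pos=[1])
        wins = pg.pi_windows(vt, population="pop1", window_bp=10,
                             contig_lengths={"chr1": 10})
        assert wins[0].value == 0.0

    def test_half_missing_site_pair_denominator(self):
        # 2 of 4 haplotypes missing -> one haplotype pair, alleles {A,T}
        vt = make_variant_table([[1, MISSING]], pos=[1])
        wins = pg.pi_windows(vt, population="pop1", window_bp=1,
                             contig_lengths={"chr1": 1})
        assert wins[0].value == pytest.approx(1.0)

    def test_dxy_fixed_difference(self):
        vt = make_variant_table(
            [[0, 2]], pos=[1], population=["pA", "pB"]
        )
        wins = pg.dxy_windows(vt, {"population": "pA"}, {"population": "pB"},
                              window_bp=5, contig_lengths={"chr1": 5})
        assert wins[0].value == pytest.approx((4 / 4) / 5)

    def test_dxy_equal_intermediate_frequencies(self):
        vt = make_variant_table([[1, 1]], pos=[1], population=["pA", "pB"])
        wins = pg.dxy_windows(vt, {"population": "pA"}, {"population": "pB"},
                              window_bp=1, contig_lengths={"chr1": 1})
        assert wins[0].value == pytest.approx(0.5)

    def test_dxy_site_with_empty_side_excluded(self):
        vt = make_variant_table(
            [[1, MISSING], [0, 2]], pos=[1, 2], population=["pA", "pB"]
        )
        wins = pg.dxy_windows(vt, {"population": "pA"}, {"population": "pB"},
                              window_bp=2, contig_lengths={"chr1": 2})
        # site 1 excluded from denominator; site 2 is a fixed difference
        assert wins[0].n_sites_compared == 1
        assert wins[0].value == pytest.approx(1.0)

    def test_fuzz_agrees_with_bruteforce(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_sites = int(rng.integers(1, 51))
            n_a, n_b = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            geno = rng.choice(
                [0, 1, 2, MISSING], size=(n_sites, n_a + n_b), p=[0.35, 0.25, 0.3, 0.1]
            ).astype(np.int8)
            span = int(rng.integers(n_sites, n_sites + 20))
            vt = make_variant_table(
                geno, pos=np.arange(1, n_sites + 1),
                population=["pA"] * n_a + ["pB"] * n_b,
            )
            pi = pg.pi_windows(vt, population="pA", window_bp=span,
                               contig_lengths={"chr1": span})[0].value
            want = brute_pi_window(geno[:, :n_a], span)
            np.testing.assert_allclose(pi, want, rtol=1e-12, equal_nan=True)
            dxy = pg.dxy_windows(vt, {"population": "pA"}, {"population": "pB"},
                                 window_bp=span, contig_lengths={"chr1": span})[0].value
            want = brute_dxy_window(geno[:, :n_a], geno[:, n_a:], span)
            np.testing.assert_allclose(dxy, want, rtol=1e-12, equal_nan=True)

    def test_self_dxy_of_halves_matches_pi(self):
        vt = syn.simulate_neutral_sfs_panel(n_diploids=20, contig_length=400_000,
                                            s_density=0.01, seed=3)
        half = np.array(["h1", "h2"] * 10, dtype=object)
        vt.population = half
        pi = pg.overall_mean(pg.pi_windows(vt, window_bp=400_000,
                                           contig_lengths={"chr1": 400_000}))
        dxy = pg.overall_mean(
            pg.dxy_windows(vt, {"population": "h1"}, {"population": "h2"},
                           window_bp=400_000, contig_lengths={"chr1": 400_000})
        )
        assert dxy == pytest.approx(pi, rel=0.05)


# ---------------------------------------------------------------------------
# FST


class TestWeirCockerham:
    def test_complete_fixation_theta_one(self):
        vt = make_variant_table(
            [[2, 2, 0, 0]], population=["pA", "pA", "pB", "pB"]
        )
        df, unw, w = pg.weir_cockerham_fst(vt, {"population": "pA"}, {"population": "pB"})
        assert df.theta.iloc[0] == pytest.approx(1.0)
        assert unw == pytest.approx(1.0) and w == pytest.approx(1.0)

    def test_no_differentiation_theta_nonpositive(self):
        vt = make_variant_table(
            [[1, 1, 1, 1]], population=["pA", "pA", "pB", "pB"]
        )
        df, _, _ = pg.weir_cockerham_fst(vt, {"population": "pA"}, {"population": "pB"})
        assert df.theta.iloc[0] <= 0

    def test_toy_matches_oracle(self):
        ga, gb = [0, 1, 1, 2], [0, 0, 0, 1]
        vt = make_variant_table(
            [ga + gb], population=["pA"] * 4 + ["pB"] * 4
        )
        df, _, _ = pg.weir_cockerham_fst(vt, {"population": "pA"}, {"population": "pB"})
        assert df.theta.iloc[0] == pytest.approx(wc_theta_oracle(ga, gb), rel=1e-12)

    def test_random_toys_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            ga = rng.choice([0, 1, 2, MISSING], size=na, p=[0.4, 0.3, 0.2, 0.1])
            gb = rng.choice([0, 1, 2, MISSING], size=nb, p=[0.2, 0.3, 0.4, 0.1])
            if len([g for g in ga if g != MISSING]) < 2:
                continue
            if len([g for g in gb if g != MISSING]) < 2:
                continue
            vt = make_variant_table(
                [list(ga) + list(gb)], population=["pA"] * na + ["pB"] * nb
            )
            df, _, _ = pg.weir_cockerham_fst(vt, {"population": "pA"}, {"population": "pB"})
            np.testing.assert_allclose(
                df.theta.iloc[0], wc_theta_oracle(ga, gb),
                rtol=1e-10, atol=1e-12, equal_nan=True,
            )

    def test_weighted_equals_unweighted_for_identical_components(self):
        row = [2, 1, 0, 0, 0, 1]
        vt = make_variant_table([row, row, row], population=["pA"] * 3 + ["pB"] * 3)
        _, unw, w = pg.weir_cockerham_fst(vt, {"population": "pA"}, {"population": "pB"})
        assert w == pytest.approx(unw)


# ---------------------------------------------------------------------------
# F_IS / Tajima / ROH / PCA


class TestFis:
    def test_fully_homozygous_individual(self):
        g = [[0, 2, 1], [2, 0, 1], [0, 0, 1]]
        vt = make_variant_table(g)
        fis = pg.fis_per_individual(vt, "pop1")
        assert fis["s0"] == pytest.approx(1.0) and fis["s1"] == pytest.approx(1.0)

    def test_fully_heterozygous_negative(self):
        g = [[1, 1, 0, 2], [1, 1, 2, 0]]
        vt = make_variant_table(g)
        fis = pg.fis_per_individual(vt, "pop1")
        assert fis["s0"] < 0

    def test_three_site_hand_value(self):
        # individual s0 over 3 sites with pop freqs from all 4 diploids
        g = [[0, 1, 1, 0], [2, 2, 1, 1], [1, 0, 0, 0]]
        vt = make_variant_table(g)
        fis = pg.fis_per_individual(vt, "pop1")
        # hand arithmetic: per site p = ac/an, E_hom = 1 - 2p(1-p)*2n/(2n-1)
        e = 0.0
        for row in g:
            p = sum(row) / 8
            e += 1 - 2 * p * (1 - p) * 8 / 7
        o_hom = 2  # sites 1 and 2 homozygous for s0
        assert fis["s0"] == pytest.approx((o_hom - e) / (3 - e))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        vt = make_variant_table([[0, 0, 0]])
        wins = pg.tajimas_d(vt, population="pop1", window_bp=10,
                            contig_lengths={"chr1": 10})
        assert np.isnan(wins[0].value)

    def test_textbook_formula_evaluation(self):
        # n=4 haplotypes (2 diploids), S=3, mean pairwise differences k
        g = [[1, 0], [1, 1], [0, 1]]
        vt = make_variant_table(g)
        wins = pg.tajimas_d(vt, population="pop1", window_bp=10,
                            contig_lengths={"chr1": 10})
        # independent evaluation with published constants at n=4
        n, S = 4, 3
        k = sum(d * (n - d) / 6 for d in (1, 2, 1))
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        want = (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert wins[0].value == pytest.approx(want, rel=1e-12)

    def test_neutral_sfs_mean_near_zero(self):
        vt = syn.simulate_neutral_sfs_panel(n_diploids=10, contig_length=500_000,
                                            s_density=0.005, seed=1)
        wins = pg.tajimas_d(vt, population="pop1", contig_lengths={"chr1": 500_000})
        vals = np.array([w.value for w in wins])
        assert abs(np.nanmean(vals)) < 0.3


class TestRoh:
    def test_all_homozygous_froh_near_one(self):
        g = [[0] if i % 2 else [2] for i in range(60)]
        vt = make_variant_table(g, pos=np.arange(1, 61) * 100)
        df, froh = pg.roh_detect(vt, "s0", min_snps=10, max_het=0, min_bp=100)
        assert froh == pytest.approx(1.0)
        assert len(df) == 1

    def test_all_heterozygous_froh_zero(self):
        g = [[1]] * 60
        vt = make_variant_table(g, pos=np.arange(1, 61) * 100)
        _, froh = pg.roh_detect(vt, "s0", min_snps=10, max_het=0, min_bp=100)
        assert froh == 0.0

    def test_single_block_detected_exactly(self):
        # 100 sites: het everywhere except a 40-SNP homozygous block at 31..70
        g = [[1]] * 30 + [[0]] * 40 + [[1]] * 30
        pos = np.arange(1, 101) * 1000
        vt = make_variant_table(g, pos=pos)
        df, froh = pg.roh_detect(vt, "s0", min_snps=10, max_het=0, min_bp=5000)
        assert len(df) == 1
        assert df.start.iloc[0] == 31_000 and df.end.iloc[0] == 70_000


class TestPca:
    def test_structured_groups_separate_on_pc1(self):
        cfg = syn.SimulationConfig(
            n_genes_per_class={"unbiased": 60},
            regimes={"unbiased": syn.neutral_regime()},
            bn_f=0.2, seed=9, missing_rate=0.0,
        )
        _, _, vt, _ = syn.simulate_genomes(cfg)
        sub = vt.subset_samples(vt.sample_mask(species="carbonaria"))
        coords, _ = pg.pca_genotypes(sub)
        pops = sub.population
        g1 = coords.PC1[pops == "carb_north"]
        g2 = coords.PC1[pops == "carb_south"]
        spread = max(g1.std(), g2.std())
        assert abs(g1.mean() - g2.mean()) > 3 * spread

    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
        g[:, 5] = g[:, 4]
        vt = make_variant_table(g)
        coords, _ = pg.pca_genotypes(vt)
        np.testing.assert_allclose(coords.iloc[4], coords.iloc[5], atol=1e-9)

    def test_explained_variance_sums_to_total(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        vt = make_variant_table(g)
        coords, evals = pg.pca_genotypes(vt, n_components=10)
        # rebuild the standardized matrix to get the total variance
        x = g.astype(float).T
        mean = x.mean(axis=0)
        p = mean / 2
        scale = np.sqrt(p * (1 - p))
        keep = scale > 0
        xs = (x[:, keep] - mean[keep]) / scale[keep]
        total = xs.var(axis=0, ddof=1).sum()
        assert evals.sum() == pytest.approx(total)


# ---------------------------------------------------------------------------
# FST x annotation


GENES = [
    GeneAnnotation("gA", "chr1", "+", [(100, 199)]),
    GeneAnnotation("gB", "chr1", "+", [(300, 349), (380, 429)]),
]


class TestFstAnnotation:
    def test_all_cds_fraction_one_and_correlation_undefined(self):
        fst = pd.DataFrame(
            {"contig": ["chr1"] * 4, "pos": [100, 150, 199, 320],
             "theta": [0.05, 0.45, 0.85, 0.95]}
        )
        table, r, _ = pg.fst_bins_cds_fraction(fst, GENES)
        occ = table.dropna(subset=["fraction_cds"])
        assert (occ.fraction_cds == 1.0).all()
        assert np.isnan(r)

    def test_constructed_rising_fraction_positive_correlation(self):
        rows = []
        pos_cds, pos_out = 100, 1000
        for b, frac in enumerate(np.linspace(0.2, 0.8, 10)):
            theta = b / 10 + 0.05
            for k in range(10):
                inside = k < round(frac * 10)
                rows.append({"contig": "chr1",
                             "pos": (100 + k) if inside else (1000 + b * 50 + k),
                             "theta": theta})
        fst = pd.DataFrame(rows)
        _, r, p = pg.fst_bins_cds_fraction(fst, GENES)
        assert r > 0.9

    def test_boundary_base_counts_as_cds(self):
        cats = pg.annotate_snp_category(
            np.array(["chr1", "chr1", "chr1"], dtype=object),
            np.array([199, 200, 360]), GENES
        )
        assert list(cats) == ["cds", "intergenic", "utr_intron"]


class TestDivergentGenes:
    def test_three_high_cds_snps_flagged(self):
        fst = pd.DataFrame(
            {"contig": ["chr1"] * 3, "pos": [110, 120, 130],
             "theta": [0.95, 0.92, 0.91]}
        )
        out = pg.flag_divergent_genes(fst, GENES)
        assert list(out.gene_id) == ["gA"]

    def test_two_snps_not_flagged(self):
        fst = pd.DataFrame(
            {"contig": ["chr1"] * 2, "pos": [110, 120], "theta": [0.99, 0.99]}
        )
        assert pg.flag_divergent_genes(fst, GENES).empty

    def test_intron_snps_do_not_count(self):
        fst = pd.DataFrame(
            {"contig": ["chr1"] * 3, "pos": [355, 360, 365],
             "theta": [0.99, 0.99, 0.99]}
        )
        assert pg.flag_divergent_genes(fst, GENES).empty

    def test_fixed_snp_intersection_strict_threshold(self):
        fst = pd.DataFrame(
            {"contig": ["chr1"] * 3, "pos": [110, 320, 500],
             "theta": [0.96, 0.95, 0.99]}
        )
        out = pg.fixed_snp_cds_intersect(fst, GENES, threshold=0.95)
        assert list(out.pos) == [110, 500]
        assert list(out.gene_id) == ["gA", ""]
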