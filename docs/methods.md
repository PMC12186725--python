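# Methods

## The question

In superorganismal insects, workers are developmentally committed to
(near-)sterility, so genes expressed mainly in workers experience selection
only indirectly, through the workers' effects on colony reproduction. Two
hypotheses make opposite predictions about the population-genetic
signatures of worker-biased genes. Under **Relaxed Constraint**, indirect
selection weakens purifying selection: worker-biased genes should show
elevated nucleotide diversity (π), elevated absolute interspecies
divergence (dxy), elevated Neutrality Index (NI), and dN/dS that is
elevated but still below one, with no elevation of relative differentiation
(F_ST). Under **Adapted Worker**, evolutionarily novel worker phenotypes
recruit recurrent positive selection: worker-biased genes should show
positive and elevated Direction of Selection (DoS), dN/dS above one, and
elevated F_ST *without* elevated dxy (recurrent sweeps of standing
variation differentiate populations faster than they accumulate fixed
differences).

The package implements the full chain needed to test this on a two-species
stingless-bee system (*Tetragonula carbonaria* / *T. hockingsi*, each with
a northern and a southern population): population-genetic statistics from a
SNP matrix, codon-aware McDonald–Kreitman statistics, a caste
differential-expression stage that defines the gene classes, and a
deterministic decision rule over the class contrasts.

## Statistics

**π and dxy** are missing-data-aware averages of per-site pairwise
difference fractions (the pixy convention). At a site with *n* called
haplotypes of which *d* carry the alternate allele, the within-group
numerator is d(n−d)/C(n,2); for dxy the cross-group numerator is
(d_A(n_B−d_B)+d_B(n_A−d_A))/(n_A·n_B). Window values divide the summed
fractions by the number of compared sites — the full window span when no
callable mask is supplied (all non-variant positions assumed callable; a
mask input is available for exactness), minus variant sites with too few
calls. Genome-wide summaries are reported both as the unweighted mean of
window values (the headline aggregation) and as the site-weighted mean.
Missing genotypes are never imputed; a missing call simply removes its
haplotype pairs from that site's comparison.

**F_ST** uses the Weir & Cockerham (1984) two-population diploid variance
components a (among populations), b (among individuals within populations)
and c (within individuals), computed from observed heterozygote counts.
Per-SNP θ = a/(a+b+c); the unweighted genome mean averages per-SNP θ
(negative values retained), the weighted mean is Σa/Σ(a+b+c). θ is
undefined where a+b+c = 0 or a population has fewer than two called
genotypes.

**Tajima's D** per window uses the 1989 constants with n set to the modal
number of called haplotypes over the window's segregating sites; windows
with S = 0 are undefined.

**F_IS** per individual is (O_hom − E_hom)/(N − E_hom) with expected
homozygosity summed over the individual's called sites using population
allele frequencies and the small-sample correction 1 − 2p(1−p)·2n/(2n−1).

**ROH**: every window of `min_snps` consecutive called sites with at most
`max_het` heterozygous calls seeds a run; overlapping seeds merge; merged
runs shorter than `min_bp` are dropped; f(ROH) is run length over assayed
span. Defaults (50 SNPs, 1 het, 100 kb) are this package's choices.

**MK statistics.** SNPs inside CDS are classified synonymous /
nonsynonymous / nonsense against the reference codon in transcription
orientation (strand-aware; nonsense counts with nonsynonymous, switchable).
Codons carrying two SNPs are classified per-SNP against the reference
codon, since phase is unavailable. Sites are polarized against the sister
species: fixed differences require strict fixation on opposite alleles (a
frequency tolerance is available); sites segregating in the focal species
count as polymorphism regardless of the sister's state, and never as
divergence. NI = (Pn/Ps)/(Dn/Ds), undefined unless Ps, Dn and Ds are all
positive; DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), undefined when either sum is
zero. −log2 NI is emitted alongside NI.

**dN/dS** uses Nei–Gojobori (1986) counting on the two species' consensus
CDSs (majority allele per site, reference on ties), with pathway averaging
for multi-hit codons (pathways through stop codons excluded when
avoidable) and the Jukes–Cantor correction d = −(3/4)ln(1−4p/3). This is a
deliberate counting substitute for maximum-likelihood codon models: it is
transparent, dependency-free and adequate for rank-based class contrasts;
it does not correct for codon usage or transition/transversion bias.

**Differential expression** is a per-gene negative-binomial log-link GLM
with caste and tissue covariates, median-of-ratios size factors as offsets,
and a per-gene method-of-moments dispersion floored at 1e-8 (no
empirical-Bayes shrinkage toward a trend — a documented simplification; the
effect sizes used in validation are large enough that shrinkage would not
change the calls). The default call is a threshold-aware Wald test of
H0: |log2FC| ≤ 1 (as in DESeq2's `lfcThreshold`), BH-corrected per
contrast; a post-hoc |LFC| filter on the ordinary β = 0 test is available
as an alternative mode. Forager and in-nest worker samples are merged into
one worker class before the queen-vs-worker contrast, mirroring the
near-absence of expression differences between the two worker groups.
Median-of-ratios normalization assumes differentially expressed genes are
a minority; validation matrices respect that.

**Class contrasts** are two-sided Wilcoxon rank-sum tests between
queen-biased, worker-biased and unbiased genes for each metric (exact null
at combined n ≤ 30, otherwise normal approximation with tie correction),
BH-corrected within each metric across its three contrasts (the correction
scope is configurable). Phylostratum composition is compared with an exact
conditional test on the 2×2 or 2×3 contingency table by full enumeration.

**Divergence dating**: T = dxy/(2μ) at one generation per year, reported
in Ma over the mutation-rate bracket μ ∈ [3.4e-9, 3.6e-9] per site per
generation (direct honey-bee and bumble-bee estimates); the higher rate
gives the younger bound.

## The verdict rule

Each hypothesis's predictions are scored from the worker-vs-queen
contrasts: +1 when the significant (BH p < 0.05) pattern matches, −1 when
the significant pattern is opposite, 0 when non-significant or ambiguous.
Relaxed predictions: worker π higher; worker dxy higher; worker NI higher;
worker dN/dS elevated with worker median ≤ 1; worker F_ST not elevated
(scored +1 only on significantly *lower*, so a fully null dataset scores
0, not spurious support). Adapted predictions: worker DoS higher with a
clearly positive worker median; worker F_ST higher without dxy elevation;
worker dN/dS higher with median > 1. A verdict of `relaxed_supported` or
`adapted_supported` requires a tally ≥ +2 with the rival tally ≤ 0; both
≥ +2 is `mixed`; anything else `inconclusive`. Two codification choices
deserve note:

- *F_ST-without-dxy*: when worker F_ST is significantly higher but worker
  dxy is also higher, the prediction is scored 0 (ambiguous), not −1 —
  positive selection modelled as extra fixed nonsynonymous differences
  necessarily raises gene dxy somewhat, and the prediction's discriminating
  content is the F_ST elevation.
- *Clearly positive DoS*: "worker median DoS > 0" is read as exceeding the
  neutral calibration band (+0.05). Per-gene DoS at sparse counts carries a
  small density-dependent bias (classes with more nonsynonymous SNPs sit a
  few hundredths above classes with fewer), which is occasionally
  Wilcoxon-significant without reflecting adaptive divergence.

The per-prediction ledger is always emitted so users can apply a different
rule.

## The synthetic data generator

The generator emulates the study's data shape with independent sites and
direct dials for every signal the pipeline measures; it is not a coalescent
simulator. A reference contig carries head-to-tail single-exon genes
(400 codons, start/stop codons intact, alternating strand, 600 bp
intergenic gaps, AT-rich intergenic sequence). Two species each contain two
populations sampled as 8 diploids.

- *Divergence*: per gene, candidate fixed differences are Poisson with mean
  L·2μT_s (μ = 3.5e-9, T_s = 600,000 generations at one generation per
  year, so 2μT_s ≈ 0.0042 — matching the observed interspecies dxy and a
  ~0.6 Ma split). Each candidate is placed uniformly in the CDS, classified
  by the genetic code, and nonsynonymous candidates are removed with
  probability f_del (the regime's purifying strength). Fixed differences
  appear as alternate-allele frequency 1 in a random one of the two
  species.
- *Polymorphism*: per gene and species, segregating sites are Poisson with
  density 0.01/bp, ancestral frequency drawn from the neutral SFS
  (P(i) ∝ 1/i over 20 chromosomes), population frequencies from the
  Balding–Nichols Beta around it (F = 0.15 between populations; realized
  within-species π ≈ 0.0016), and genotypes binomial per diploid.
  Nonsynonymous candidates are thinned by the same f_del. 2% of genotypes
  are set missing.
- *Regimes*: neutral (f_del = 0), purifying (f_del = 0.8), relaxed
  (f_del = 0.1), positive (k_sweeps = 3 extra forced nonsynonymous fixed
  differences plus a locally raised F = 0.45 at the gene's polymorphic
  sites, standing in for recurrent local selection).
- *Expression*: negative-binomial counts (dispersion 0.1) for 4 castes × 2
  tissues × 3 colonies, baselines log-normal (log2 mean 6, sd 2), |log2FC|
  = 3 between queen and the two worker groups for biased genes (males at
  baseline, forager and in-nest worker sharing means), a per-gene tissue
  effect (log2 sd 0.5) and per-sample depth factors (log2 sd 0.3).
- A separate *neutral-SFS panel* mode places exact derived-allele counts
  drawn ∝ 1/i on random chromosomes of a single population; by
  construction the Tajima's D numerator has zero expectation, which is the
  calibration bed for the window machinery.

What the generator does **not** model: linkage and sweep-linked diversity
loss, recombination, demography, selection on expression, multi-exon
genes with phase ≠ 0 (the GFF3 reader handles them; the generator does not
emit them), and shared ancestral polymorphism. Passing tests therefore
demonstrate estimator correctness and end-to-end signal recovery under
idealized independence, not robustness to linked selection or demographic
confounding on real data.

## Numerical and scale choices

Analysis-scale runs use 300 genes per class (900 genes, ~33k SNPs, 32
diploids), which gives the Wilcoxon contrasts overwhelming power at the
imposed effect sizes while keeping a full scenario under ~10 s; the
expression validation uses 1,000 genes at the study's 24-sample design.
Dispersion estimates are floored at 1e-8; GLM fits are IRLS to tolerance
1e-8 with a 100-iteration cap, and non-converged genes are flagged and
excluded from calls. Ties in consensus building fall back to the reference
base; negative per-SNP θ is retained in means and clamped only for
binning. The MAF filter boundary is inclusive (≥ 0.05), and the
"allele count of 50" completeness filter is interpreted as a minimum
number of *called* alleles (AN ≥ 50) — an ALT-count floor of 50 would
contradict a 0.05 MAF threshold at the study's sample size.

## Known limitations

Per-gene NI is upward-biased at sparse counts (conditioning on Ds ≥ 1
dominates when the expected synonymous divergence per gene is ~1), so its
neutral median sits near the top of its calibration band; DoS is the
better-behaved statistic at these densities, consistent with its original
motivation. Effective length is the summed CDS length, not a
quantifier-style fragment-corrected length. LD pruning is a greedy
left-to-right scan whose survivor set can differ from PLINK's
window-pairwise variant. The 2×3 exact test enumerates the full table
space and is intended for class-count tables, not for margins in the many
thousands.
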