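# Methods

## Screen model

### Generative model of a two-bin sorted screen

A pooled knockout library of `n_genes × guides_per_gene` targeting guides
plus safe-targeting (and optionally non-targeting) controls is sorted into
the low and high tails of a melanin-proxy distribution (side scatter). The
generator (`synth.simulate_screen`) draws, per replicate:

- per-guide efficacy `u_i ~ Uniform(0,1)`, independent across replicates;
- baseline guide abundance `a_i = 2^Normal(0, abundance_log2_sd)`
  (default 0.25 — modest library skew; it cancels in the log-ratio);
- bin frequencies `f_low ∝ a_i·2^{+u_iθ/2}`, `f_high ∝ a_i·2^{−u_iθ/2}`,
  so `E[log2(f_low/f_high)] = u_i·θ_g` exactly;
- counts `NB(mean = depth·G·f, variance = μ + αμ²)` with dispersion
  α = 0.1 by default (gamma–Poisson mixture; α = 0 gives Poisson).

Sign convention throughout: θ > 0 ⇔ the knockout lowers the melanin proxy
⇔ guides enrich in the low bin. Depth (500 reads/guide/bin) and dispersion
are free parameters of the generator — realistic values for a deep-sequenced
pooled screen — since sorted-screen count distributions vary widely between
experiments; both are config fields.

The uniform-efficacy assumption is deliberately shared between generator
and estimator: the estimator's convolution likelihood is exactly the
marginal density of `e` under the generative model, making parameter
recovery a meaningful self-consistency check. What the generator does *not*
model: guide-specific off-target effects, sort impurity/cross-contamination
between bins, PCR jackpotting beyond NB dispersion, and cell-cycle or
fitness coupling to the sort phenotype. Passing recovery tests therefore
demonstrate correctness of the estimator under its own model, not
robustness to every artifact of real screens.

### Estimation

- **Enrichment**: `e_i = log2((c_low+pc)/(N_low+pc·G)) −
  log2((c_high+pc)/(N_high+pc·G))`, pseudocount 0.5, centered by the median
  of safe-targeting controls (falling back to non-targeting, then both
  pooled, when a class is absent — libraries differ in which control class
  they carry).
- **Null**: Gaussian KDE of control enrichments with Silverman's
  rule-of-thumb bandwidth `h = 0.9·min(sd, IQR/1.34)·n^{−1/5}`, evaluated on
  a ≥512-point uniform grid spanning the data ±3h, trapezoid-renormalized
  and floored at 1e-10 (keeps out-of-range observations at finite
  log-likelihood). At least 50 controls are required.
- **Likelihood**: `p_θ(e) = (P0(e) − P0(e−θ))/θ` via the interpolated
  cumulative of the null grid; for |θ| below one grid step a two-point
  trapezoid of interpolated densities is used instead, which converges to
  `p0(e)` as θ → 0 (continuity of the uniform convolution at zero width).
  θ grid: 401 points on [−8, 8] log2 units; ties in the argmax break toward
  smaller |θ|; natural-log likelihoods; CI = grid points within the
  χ²₁ 95% cutoff (3.841) of the maximum.
- **Empirical FDR**: pseudo-genes resample control enrichments with
  replacement, guide counts drawn from the real genes' guide-count
  distribution; default 10 pseudo-genes per real gene.
  `FDR(s) = [(#pseudo ≥ s)/n_pseudo]/[(#real ≥ s)/n_real]`, capped at 1 and
  monotonized BH-style (each gene takes the minimum FDR over thresholds at
  or below its score), so FDR is non-increasing in score. Hits require
  θ̂ > 0 — only melanin-*promoting* knockouts are called; the negative tail
  is out of scope — and FDR < 0.1 in every replicate.

Median θ̂ recovers planted θ = 2 within a few percent at depth 500 with 10
guides/gene; the uniform-efficacy marginal makes θ̂ a consistent estimator
of the *full* effect despite per-guide attenuation.

## PBS scan

Hudson's estimator is used for pairwise F_ST (the standard per-SNP choice
for two-population scans; it needs no weighting decisions):

```
N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),   D = p1(1−p2) + p2(1−p1)
```

with F = N/D (0 when D = 0, i.e. both populations fixed for the same
allele), clamped to [0, 1−1e-6] before `T = −ln(1−F)`; the clamps prevent
negative branch lengths from finite-sample noise and infinite lengths at
fixation. The log base is a global monotone rescaling of PBS and does not
affect ranks, quantile flags or empirical p-values. Empirical p is the
self-inclusive genome-wide rank `p_i = #{PBS_j ≥ PBS_i}/N` (not
per-chromosome); quantile thresholds take the ⌈level·N⌉-th largest value
with ties included. Gene windows are ±100 kb around gene bodies, 1-based
closed intervals, clipped at position 1; a SNP inside several windows is
assigned to each gene. No MAF filter is applied by default.

The three-population generator uses the Balding–Nichols model
(`Beta(p(1−F)/F, (1−p)(1−F)/F)` around a Uniform ancestral frequency),
drift F = 0.01 per population by default and 100 diploid samples per
population, with planted selection as a +Δ frequency shift in the target
population, clipped to [1/(2n), 1−1/(2n)]. It models no linkage
disequilibrium, recombination or ascertainment — each SNP is independent —
so recovery tests measure ranking behavior of the statistic, not
haplotype-scale signal.

## Concordance statistics

- Lead eQTL per gene: minimum p among records with p < 0.01; ties break by
  smaller |distance| to the gene, then (chrom, pos).
- Harmonization: GWAS β is sign-flipped when its effect allele is the
  eQTL's other allele; A/T and C/G pairs are dropped as strand-ambiguous;
  allele sets matching neither orientation are dropped with a logged count.
  Harmonization is involutive: re-harmonizing harmonized output is a no-op.
- Sign concordance: two-sided exact binomial at p₀ = 0.5, defined as twice
  the smaller tail capped at 1 (for 7/7 agreements this is
  2·(1/2)⁷ = 0.015625). Zero effects are dropped with a warning.
- Fisher 2×2: the *sample* odds ratio (a·d)/(b·c) is reported (∞ when
  b·c = 0 with a·d > 0, undefined 0/0 as missing) with the exact
  conditional two-sided p. For the table (8, 161, 322, 19722) the sample
  OR is ≈ 3.04; a published value of 3.19 for these margins corresponds to
  no standard estimator we could identify (conditional-MLE gives ≈ 3.04 as
  well), so the sample OR is reported and the discrepancy documented rather
  than matched.
- PBS × GWAS: Spearman with midrank ties and t-approximate p; the
  stratified comparison is a two-sided Wilcoxon rank-sum
  (normal approximation with tie and continuity correction) of GWAS β
  between SNPs with PBS empirical p < 0.01 and the rest.

The pair generator couples `β = s·κ·slope + noise` with a sign flip `s`
at probability `discord_prob`, and Wald-style p-values decreasing in
|effect| (standard errors at half the effect scale, so roughly the top
fifth of genes pass p < 0.01 — a filter severity comparable to lead-eQTL
selection). A configurable fraction of GWAS rows reports the opposite
allele (β negated) to exercise harmonization.

## Expression–melanin correlations

Spearman ρ per gene against donor melanin OD400, two-sided p via the
t-approximation with n − 2 df (adequate at n = 30; an exact permutation
p is available behind a flag), Benjamini–Hochberg q-values over all tested
genes (the conservative default among FDR methods), strict q < 0.1 for
significance, and "measurable" defined as TPM > 0 in every sample. As a
consistency check on the t-approximation, the |ρ| rejection boundary
implied by 119 rejections out of 158 tests at FDR 0.1 with n = 30 is
0.3296 ≈ 0.33 (`exprcorr.implied_rho_cutoff`).

The generator uses `log2 TPM = a_g + b_g·m_s + ε` with melanin
m ~ Uniform(0.1, 2.0) OD units, intercepts a ~ Normal(5, 2) (TPM ~ 32 at
baseline), |b| half-normal with scale 1.0 per OD unit, noise sd 1.0, and
the planted positive/negative fractions defaulting to the 107:12:39
proportions of a 158-gene hit panel. With these scales roughly a third to
a half of the planted genes are individually detectable at q < 0.1 with
n = 30 — weak-slope genes are real but undetectable, as in any finite
panel — while sign accuracy among detected genes exceeds 90%.

## Problem sizes and numerical choices

- Screen recovery runs at 1,000 null + 100 planted genes (θ = 2), 10
  guides/gene, depth 500, two replicates — a desk-scale version of a
  genome-wide screen preserving the guide-to-control ratio; it completes in
  seconds because all gene × θ likelihoods are evaluated as vectorized
  CDF differences.
- Null calibrations use 200-gene single-replicate screens over 20 seeds,
  and 400–1000 Monte-Carlo replicates per test; the binomial calibration
  uses 500 pairs per replicate so test discreteness does not dominate the
  rejection rate.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; identical config + seed is bit-reproducible, and
  the pipeline manifest records every stage seed and output checksum.
- Degenerate inputs are errors, not silent results: constant controls
  (zero KDE bandwidth), empty strata, mismatched gene universes or sample
  sets, unmapped VCF samples.

## Known limitations

- The screen likelihood treats guides as exchangeable within a gene: no
  per-guide efficacy covariates, no variance shrinkage across genes, no
  negative-tail (melanin-suppressing) calling.
- PBS empirical p-values are genome-wide ranks, not calibrated tail
  probabilities; with simulated-independent SNPs they are exact ranks, with
  real linked data they are descriptive.
- Harmonization handles allele orientation only; it cannot rescue
  strand-ambiguous variants and performs no frequency-based inference.
- The expression stage tests marginal correlations; it does not model
  donor covariates, batch, or ancestry structure.
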