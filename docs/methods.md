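# Methods

## Disease model

All architecture math assumes a liability-threshold model: each
individual has a latent liability `L = G + ε` with `ε ~ N(0, 1)`, and is
affected iff `L > t`, where `t` is set so the population prevalence is
`K` (`t = Φ⁻¹(1−K)` when `G` has mean 0 and is absorbed into the
threshold). A biallelic unit with risk-allele frequency `p` and odds
ratio `OR` is placed on this scale by solving the per-genotype
penetrances

    odds(f_g) = OR^g · odds(f_0),   Σ_g HWE_p(g) · f_g = K,

(1-D monotone bisection on `logit f_0`) and assigning each genotype the
liability mean `μ_g = t + Φ⁻¹(f_g)` that reproduces `f_g` under the unit
residual. The liability variance explained is then

    LVE = Var_g(μ_g) / (Var_g(μ_g) + 1).

Gene burdens are treated as biallelic carrier pseudo-variants at their
combined MAF, because the pipeline's burden odds ratios are carrier-level
quantities. The construction is validated in the tests against a direct
10⁷-draw simulation of the threshold model (agreement well within 10%
relative). Penetrance saturation (`1 − f_g < 1e−10`, i.e. a liability
shift beyond ~6.4 SD) raises an error naming the genotype: beyond that
point the probit mapping is numerically meaningless and such an effect
is better modelled as fully penetrant.

Per-unit LVE contributions are summed assuming independence (no LD in
the synthetic data; real exome units on different genes are nearly
independent). Aggregate confidence intervals are percentile bootstrap:
estimates are redrawn from `N(β_corrected, SE²)`, re-corrected draw by
draw, converted to LVE and summed. The bootstrap rather than the delta
method because the winner's-curse correction is nonlinear.

## Winner's curse

Selected estimates (`|β̂|/SE > z_c` at discovery) are de-biased by the
conditional MLE: the `β` maximizing the normal density of `β̂` truncated
to the selection region, found by ~200 bisection steps on the score
function over `[0, |β̂|]` (the estimator never exceeds the naive estimate
in magnitude and keeps its sign; at `z_c = 0` it is the identity). The
implementation is vectorized so the bootstrap can re-correct hundreds of
thousands of draws at once; it matches a 400k-point grid-search oracle
to better than 1e−3.

A property users should know: conditional on selection, the CMLE
overshrinks on average in the moderate-selection regime (true `β/SE`
near the threshold). At `β = 0.3, SE = 0.12, z_c = 1.96` the naive mean
is +0.06 biased and the corrected mean is −0.03 biased. This is a known
cost of the estimator itself (compromise-weighted alternatives exist but
are not implemented); the tests assert bias reduction, not elimination.

## Shared controls and cross-study comparison

When two case-control studies share `n_s` controls, the delta method on
`logit(p̂_case) − logit(p̂_ctrl)` gives the estimate covariance
`n_s / (n_ctrl1 · n_ctrl2)` (per unit of `1/(2pq)`), hence

    r = [ n_s0 √(c1 c2 / d1 d2) + n_s1 √(d1 d2 / c1 c2) ]
        / √((c1+d1)(c2+d2))

with `c` cases, `d` controls, and `n_s0`/`n_s1` shared controls/cases
(the shared-case term makes `r → 1` as the designs coincide). The closed
form is validated against a 500-replicate overlapping-study simulation
(binomial allele counts, shared control pool) and the API falls back to
the simulated value if they ever disagree by more than 0.05.

The expected cross-study exceedance frequency (how often the smaller
study's raw estimate exceeds the discovery study's *corrected* estimate
under equal true effects) is computed by Monte Carlo over correlated
bivariate-normal estimate pairs, conditioning on each study's selection
threshold and applying the CMLE to the discovery-study draws. With the
two studies' sample sizes, 9,777 shared controls, nominal selection in
both studies, and a shared true log OR of 0.433 at 1% carrier frequency,
the expected frequency is ≈60% — the reference point against which an
observed exceedance rate is tested by an exact binomial tail.

## Synthetic cohorts

The generator (`burdenarch.cohort`) emulates the statistical structure
of a multi-ancestry exome study:

- **Structure.** Per-cluster allele frequencies follow a
  Balding–Nichols beta around a shared ancestral frequency with the
  cluster's differentiation parameter (F_ST ≤ 0.25). Variants with
  ancestral MAF below `drift_maf_floor` (default 1%) keep their
  ancestral frequency: rare alleles are young and nearly undrifted, and
  letting them drift at common-variant F_ST would make a gene's
  combined MAF wildly unstable across clusters.
- **Effects.** Common causal variants get per-genotype liability means
  from the penetrance construction above. Rare effects are specified at
  the gene (burden) level and distributed over the gene's variants in
  proportion to a deleteriousness weight (PTV 1.0, strict missense 0.7,
  broad missense 0.3, synonymous 0), scaled so the mean shift among
  gene carriers reproduces the configured carrier OR. Stricter masks
  therefore show larger effects, as in real collapsing analyses.
- **Ascertainment.** Cases and controls are collected by rejection
  sampling within each cluster until the configured counts are exact;
  the threshold is set from the analytic mean/variance of the genetic
  score (normal approximation). Genotypes at null variants, which
  cannot influence ascertainment, are drawn only for kept samples. The
  realized pre-ascertainment prevalence and the number of liability
  draws are stored on the cohort; infeasible requests (prevalence too
  small for the cap on draws) raise rather than truncate.
- **Monogenic variants.** Pathogenic-flagged variants in registry genes
  are assigned a penetrance directly: carriers become cases with that
  probability, bypassing the liability score. The population carrier
  frequency is derived from the target case-carrier rate by Bayes
  (`p_carrier = rate · K / penetrance`), split evenly across registry
  genes. A configurable "mixed" registry gene additionally carries
  ordinary rare risk variants, so leave-carriers-out re-analysis has
  both an attenuating and a persisting gene to find.
- **Phenotypes.** Age at diagnosis (cases only), BMI Z-score and
  log10 C-peptide are linear in the standardized true rare / common
  log-OR scores plus MODY-carrier shifts plus independent Gaussian
  noise. Defaults: age slope −0.102 y/SD of rare score, C-peptide slope
  0.040 log10/SD of common score, MODY shifts −0.9 y / −0.38 SD /
  −0.12 log10, baselines 13.6 y, 2.18 (cases) / 1.2 (controls) BMI-Z,
  0.55 log10 C-peptide, noise SDs 2.3 / 0.57 / 0.33. No pleiotropy:
  phenotypes depend on genotypes only through the true scores, which
  makes the score-phenotype regressions exactly identifiable.

What the generator does **not** emulate: linkage disequilibrium within
or between genes, relatedness, sequencing/genotyping error, batch
effects between case and control sequencing, site-frequency-spectrum
realism beyond the configured ranges, and ancestry-specific effect
sizes. Passing tests therefore demonstrate that the statistical
machinery is correct under its stated model, not that the pipeline is
robust to these real-data complications (external-control batch
artifacts in particular are the dominant practical risk this design
cannot probe).

## Ancestry matching

PCs come from an SVD of the standardized case dosage matrix after
MAF ≥ 5% filtering and windowed r² > 0.2 pruning; signs are fixed by
making each component's largest-magnitude loading positive, and
controls are projected with the case means/SDs. Cluster labels are
seeded k-means on the top PCs. Matching is greedy: rounds over cases in
lexicographic sample-id order (determinism), each case claiming its
nearest unused control within the caliper, up to `max_ratio` controls
per case. The default caliper is the mean plus two SDs of the pairwise
case-case PC distance — wide enough to retain essentially all controls
drawn from the cases' own ancestry mixture (a tight caliper starves the
later greedy rounds), while still excluding a population displaced by
ten SDs on a leading PC. Both the caliper and the ratio are explicit
knobs.

## Association testing

Masks cross consequence classes with MAF ceilings evaluated on
control-only frequency, so case enrichment cannot leak into mask
membership; variants absent from controls still qualify if observed at
all (they are exactly the case-enriched variants burden tests exist
for). The mask ladder is made nested by construction — mask k's variant
set is the union of raw rules 1..k — which guarantees monotone carrier
sets for any rule list. Defaults: PTV@0.1%, +strict missense@0.1%,
@0.5%, +broad missense@0.1%, @0.5%, all nonsynonymous@1%, @5%, plus a
separate synonymous-only negative-control mask.

Per-mask burden tests use Firth-penalized logistic regression when the
exposure has fewer than 50 minor-class carriers (plain ML otherwise,
with a Firth rescue on separation). Burden P-values come from the
profile penalized likelihood-ratio test (the coefficient constrained to
zero with the penalty kept at the full design), which is well calibrated
down to ~10 carriers where the Wald statistic is conservative;
single-variant tests report conventional Wald P-values. The per-gene
minimum P over masks is corrected with the effective test count — the
number of leading eigenvalues of the inter-mask carrier correlation
matrix needed to reach 99.5% of its trace — via
`P_corr = 1 − (1−minP)^N_eff`, validated against a 10,000-permutation
min-P oracle (agreement within a factor 1.5 for P in [0.001, 0.5]).
Pooled regression with cluster-indicator covariates is the default;
fixed-effect inverse-variance meta-analysis across clusters is
available (`meta_fixed_effect`).

## Enrichment and tiers

Hypergeometric over-representation uses the exact tail; fold is
`(overlap/|top|)/(|set∩universe|/|universe|)`. Rank-sum enrichment is
one-sided (set P-values smaller than background) against a background
matched on decile bins of variant count × combined MAF, sampled (seeded)
at 10× the target size; the fold for rank-sum results is the ratio of
nominal-significance fractions, reported as missing when the background
has none (both the fold definition and the Benjamini–Hochberg q-values
on hypergeometric P's are this package's documented choices; other
groups define them differently). Tiering: tier 1 exome-wide corrected P;
tier 2 adds top-K genes in monogenic-diabetes/causal-coding lists;
tier 3 adds top-K genes in ≥2 enriched metabolic sets; tier 4 is
nominal-significance membership of an enriched metabolic set; each gene
takes its smallest qualifying tier.

## Contribution scores and bands

Rare scores add the corrected log OR once per carried gene (burden ORs
are carrier-level); common scores add `weight × (dosage − 2·AF_ctrl)` —
centering at the control-mean genotype makes the score OR read as risk
relative to the population-average genotype, without which the
population-wide sum of hundreds of weights swamps any banding threshold.
The combined score is the log-scale sum. Bands are assigned once per
sample with precedence MODY > rare > common > combined at OR ≥ 5, then
the same order for 3–5. The rare-share trend restricts to combined
OR ≥ 3 with both components positive, ranks by combined score, and
reports per-bin means plus a Spearman trend statistic. Phenotype
regressions are OLS of each phenotype on the standardized score plus sex
and cluster indicators, cases only, MODY carriers excluded; MODY
carriers are compared by Welch t-tests (Mann–Whitney behind a flag).

## Numerical choices

- Logistic Newton iterations: tol 1e−9 on the step ∞-norm, 60
  iterations, per-step cap 5.0 (guards near-separated fits).
- CMLE and penetrance solves: 200 bisection steps on provably
  sign-changing monotone score functions.
- Nearest-neighbour ties in matching broken by control sample id.
- P-values serialized in 6-significant-digit scientific notation.
- All randomness flows from one `numpy.random.Generator` per run; the
  manifest records the seed, and identical config + seed reproduces
  identical non-stochastic outputs byte-for-byte.

## Problem sizes used in the tests and acceptance run

Desk-scale sizes chosen for the test suite (the generator's scientific
defaults — prevalence 1%, ~3,000 cases, ~9,800 controls, OR and MAF
ranges — are unchanged): calibration and oracle cohorts use 500–1,000
cases with 1,000–2,000 controls and 40–1,000 null genes; type-I error is
measured over ~1,000 independent null burdens; recovery coverage uses
100 replicate cohorts of 600 cases; the LVE fold-change recovery uses
100 summary-statistic replicates with 300 bootstrap draws; the
permutation oracle uses 10,000 label permutations. The acceptance script
runs the banding cohort at the full 3,005-case scale.

## Known limitations

- The matching approximates the reference SVD-based method by
  projection plus greedy nearest neighbours; it is deterministic and
  near-optimal at these scales but not an optimal assignment.
- `N_eff`-corrected min-P is an approximation to the permutation null;
  the factor-1.5 agreement band is empirical, driven by per-mask P
  discreteness at small carrier counts.
- Aggregate LVE assumes independent units and a correctly specified
  threshold model; with strong LD or mis-specified prevalence the
  totals shift (a prevalence sensitivity grid is part of the pipeline
  output).
- The CMLE's conditional overshrinkage (above) propagates into any
  quantity built on corrected estimates.
- Phenotype regressions on *estimated* (rather than true-weight) scores
  are attenuated by weight-estimation noise; the pipeline reports them
  as observational associations, not causal effect sizes.
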