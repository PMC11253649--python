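# Methods

This note documents the statistical model behind `mrmediate`, the
numerical conventions it fixes, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Two-sample MR model

The package works entirely on GWAS summary statistics. For an exposure E
and outcome O, each SNP j contributes an exposure association
(β̂_exp,j, se_exp,j) and an outcome association (β̂_out,j, se_out,j) from
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, exchangeability, exclusion restriction) every valid SNP
satisfies β_out,j = θ·β_exp,j, and the per-SNP Wald ratio
r_j = β̂_out,j/β̂_exp,j estimates the causal effect θ (log-odds per
exposure unit for a binary outcome).

### Ratio standard errors and weights

The default per-SNP ratio se is the first-order delta approximation
se_out,j/|β̂_exp,j|, which ignores exposure-side sampling error (the NOME
approximation); inverse-variance weights are its reciprocal square. A
second-order option adding β̂_out²·se_exp²/β̂_exp⁴ is provided. Two
consequences of the first-order default are worth knowing:

- Cochran's Q is inflated when the outcome GWAS is much more precise than
  the exposure GWAS and the effect is large — the neglected exposure noise
  masquerades as heterogeneity. The inflation factor is roughly
  1 + θ²·(n_out_eff/n_exp).
- IVW is attenuated by the regression-dilution factor ≈ z̄²/(z̄²+1),
  negligible for instruments with z ≳ 8 (< 2%).

### Estimators

- **IVW** (k ≥ 2): fixed-effect weighted mean of ratios; se = (Σw)^{-1/2}.
  A multiplicative random-effects flag inflates the se by
  max(1, sqrt(Q/(k−1))). Normal inference.
- **MR-Egger** (k ≥ 3): weighted regression of β̂_out on β̂_exp with free
  intercept, weights 1/se_out². SNPs are oriented so every exposure beta
  is non-negative before fitting (flipping both betas together), making
  the fit invariant to per-SNP sign conventions. Closed-form 2-parameter
  WLS; coefficient covariance scaled by the weighted residual variance
  with Student-t inference on k−2 df (verified against statsmodels WLS to
  1e-9). A residual variance that vanishes to rounding (the exactly
  collinear construction) is reported as se 0 with a NaN p — a degenerate
  boundary case, not an error. MR-Egger's slope is only identified when
  instrument strengths genuinely vary; with near-constant strength it
  suffers severe errors-in-variables attenuation, which is why the
  generator spreads strengths (below).
- **Weighted median** (k ≥ 3): order ratios, form cumulative standardized
  weights p_j = (S_j − w_j/2)/S_total, and linearly interpolate at
  p = 0.5. The se comes from a seeded parametric bootstrap redrawing both
  betas from their sampling distributions (default 1000 draws; 0 skips the
  bootstrap and leaves se/p as NaN). Plain inverse-variance weights, not
  penalized. Under the interpolation formula a SNP holding > 50% of the
  weight pins the estimate only up to interpolation against its
  neighbours, so "dominant weight returns that ratio" holds to a small
  fraction of the neighbour gap rather than exactly.
- **Wald ratio** (k = 1): the single-SNP base case; pipelines fall back to
  it automatically when only one instrument survives.

All odds-ratio presentation uses OR = exp(β), 95% CI = exp(β ± 1.959964·se)
— so the OR is always the geometric mean of its CI bounds, which is also
how printed ORs can be recomputed from printed intervals.

### Diagnostics

- **Cochran's Q** = Σ w_j (r_j − β_IVW)² on k−1 df, fixed-effect
  first-order weights (consistent with the IVW default).
- **Egger intercept test**: intercept row of the Egger fit, t on k−2 df.
  Calibrated (0.05 ± 0.02 at 2000 replicates) under a balanced-pleiotropy
  null with homoscedastic weights; heteroscedastic outcome ses combined
  with a constant pleiotropy variance would leave the weights misspecified
  — a property of the estimator, not of this implementation.
- **MR-PRESSO**: data are standardized by the outcome se; for each SNP the
  zero-intercept slope is re-fit without it, and the squared standardized
  residual against that leave-one-out prediction accumulates into the
  observed RSS. The null is parametric: outcome betas are redrawn around
  their leave-one-out predictions (exposure betas held fixed — a
  simplification of the published resampling) `n_sim` times, all seeded.
  Global p is the empirical tail with the +1 correction; per-SNP outlier
  p-values are empirical tails Bonferroni-corrected by k (so the smallest
  attainable corrected p is k/(n_sim+1); n_sim = 1000 resolves outliers
  at the 0.05 level for panels up to k = 50). The distortion test compares
  the estimate without the flagged outliers against a null of removing
  equally many random SNPs — an adaptation of the published counterfactual
  resampling. The outlier test needs k ≥ 4; below that only the global
  test runs, with a notice.
- **Leave-one-out**: IVW re-estimated k times; omissions that flip the
  sign or cross the α significance boundary are flagged.

### Decision rules

Given diagnostics at level α (default 0.05): pleiotropy promotes MR-Egger;
otherwise heterogeneity promotes the weighted median; otherwise IVW is
preferred. Independently, an analysis with *both* tests significant is
excluded outright. Screening significance is judged on the IVW p-value,
while the reported primary estimate follows the ladder — this reconciles
the two conventions found in screening studies of this design. NaN
diagnostics (degenerate or unavailable) count as no evidence, never as
significance. MR-PRESSO outliers are removed once, with the removal
logged, and diagnostics and estimates recomputed; removal is a visible,
configurable step (`remove_presso_outliers`), never silent.

One consequence the user should expect: the ladder's promotions are
triggered by hypothesis tests with a 5% false-positive rate, so in roughly
one screen in twenty the primary estimate switches to MR-Egger (markedly
noisier) or the weighted median (~35% less efficient) on a perfectly clean
panel. That is faithful behaviour of the rule, not a bug.

### Multiple testing

No correction is applied across the trait catalogue by default (screening
at raw p < 0.05, matching the emulated workflow); Benjamini–Hochberg is
available via `bh_correction`. On an all-null catalogue the significant
fraction is therefore ≈ α by construction, and a 20-trait screen with 17
nulls produces ≥ 1 false positive in about half of random datasets —
tests assert full recall of planted effects plus a binomial envelope on
false positives, and exact recovery under BH.

### Reverse MR

Significant pairs are re-run with outcome and exposure swapped, the
disease side instrumented at 1×10⁻⁵ (configurable; the case-control GWAS
being emulated has too few cases for 5×10⁻⁸ hits). A reverse IVW p < α
sets the bidirectional flag. Limitation: without Steiger directionality
filtering (out of scope), a well-powered outcome GWAS contains the
forward-causal loci among its hits, and naive reverse MR will read the
reflected forward effect as reverse causation. The bundled unidirectional
test scenarios therefore keep forward effects small relative to the
outcome GWAS's resolution; with genuine feedback the reverse estimate is
a mixture of the feedback path and reflected forward signal, so only its
significance is interpretable.

### Mediation

b = β1·β2, direct = β0 − b (stored exactly in that form, so the
decomposition identity is bit-exact by construction), proportion b/β0
when β0 ≠ 0, classification by sign agreement of b and β0. The se of b is
the delta-method form sqrt(β1²·se2² + β2²·se1²) — an uncertainty statement
beyond the bare decomposition, validated against Monte-Carlo within 5%.
The three betas entering a triplet come from each screen's decision-rule
primary estimator, for consistency with the preference ladder. β1 is on
the mediator's SD scale and β2 per mediator SD; the generator enforces
this shared scale.

## The synthetic-data generator

`simulate_triplet_gwas` draws one exposure→mediator→outcome triplet under
the standard summary-statistic simulation model: true per-SNP exposure
effects γ_j (z-score parameterized, optionally spread uniformly over
z·(1±spread)), mediator truth θ_EM·γ_j, outcome truth
θ_direct·γ_j + θ_MO·θ_EM·γ_j + α_j with pleiotropic shortcuts α_j on an
`invalid_fraction` of instruments, and independent Gaussian estimation
noise per study with se = 1/sqrt(2·maf·(1−maf)·n). The binary outcome is
simulated directly on the log-odds scale with the effective sample size
n_eff = 4·n_cases·n_controls/(n_cases+n_controls) — exactly an
se-inflation of sqrt(0.25/(φ(1−φ))) relative to a balanced design, which
is how a severe case-control imbalance enters. p-values satisfy the
normal Wald relation to the generated (beta, se) by construction, and all
generation is a pure function of (scenario, seed).

Scenario defaults mirror the emulated study scales (exposure n ≈ 18,340;
mediator n ≈ 8,299; 91 cases / 174,006 controls); at those scales the
outcome side is extremely noisy, which is the realistic regime.
`CausalScenario.powered()` is the large-n preset used for
parameter-recovery checks.

`simulate_screen_world` builds a miniature three-source study over a
shared SNP panel (default 20 microbial taxa with the printed five-rank
composition scaled down, 30 metabolites, one disease, LD blocks of two
SNPs at r² = 0.9, null SNPs): taxa #0 and #1 act through metabolite #0,
taxon #2 acts directly, metabolite #1 is independently protective, all
else is null; `write_fixture_suite` writes it as canonical TSVs plus a
JSON truth manifest, byte-identical per seed. The fixture's sample sizes
and instrument counts are deliberately *powered test-fixture* conditions,
not realistic ones: the exposure→mediator precision trades off exactly
against contamination of the mediator's GWAS by exposure loci (per-SNP
ratio se × borrowed-locus z = θ_EM, an identity), so identifying the
mediated effect to ~5% at desk scale forces a very large exposure GWAS
(n = 640,000) with many moderate instruments, while the NOME Q-inflation
above caps the outcome-to-exposure precision ratio. These sizes were set
by that power analysis and then validated over a 20-seed sweep before
being frozen.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic LD structure beyond
block-constant r², population stratification, sample overlap between the
two samples, winner's-curse selection in the discovery GWAS (instruments
are drawn at their true strength), compositionality of microbial
abundance, non-Gaussian effect-size distributions, and any biology in the
trait names.

## Numerical conventions

- CI multiplier fixed at 1.959964; p-values floored at 1e-300 so the
  (0, 1] invariant survives underflow.
- Clumping ties broken by (p, chromosome label, position); all pipelines
  are deterministic given inputs, config and seed.
- Emitted tables use `%.10g` float formatting, making re-runs
  byte-identical; summary-statistics TSVs use shortest round-trip float
  repr, so write→read reproduces records bit-exactly.
- Bootstrap, MR-PRESSO and generator seeds are explicit parameters
  (default 0).
- Palindromic SNPs (A/T, C/G) are dropped by default; the `infer` policy
  retains them when both panels report an effect-allele frequency outside
  [0.42, 0.58], oriented by minor-allele agreement. Duplicated SNP ids are
  rejected at read time with a per-row report rather than deduplicated.
- Filter order is p-value → clump → F → confounders, so clumping sees the
  full significant panel.

## Problem sizes used in the test suite

Calibration tests use 2000 replicates (k = 10 panels); robustness 500
replicates (k = 30); MR-PRESSO behaviour 100 runs at n_sim = 1000
(k = 15); coverage 500 replicates with a 60-draw bootstrap; the
end-to-end fixture is the default screen world (≈ 3,600-SNP panel, 51
trait files). The full suite runs in under a minute on one CPU, the
acceptance script in about twenty seconds.
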