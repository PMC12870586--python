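# Methods

`pwaskit` replicates, on synthetic family-structured cohorts, the
statistical machinery of a proteome-wide association study of cognitive
function and incident dementia: hundreds of correlated mass-spectrometry
protein signals tested against several correlated continuous outcomes,
against APOE ε4 genotype, and against time-to-dementia, all while
absorbing family resemblance through a relatedness matrix.

## Relatedness convention

Throughout, the kinship argument `K` is the expected genetic relatedness
matrix: diagonal 1, full siblings 0.5, unrelated individuals 0. This is
*twice* the kinship coefficient — it is the matrix a Gaussian random
effect consumes directly as its covariance scale (`g ~ N(0, σ²_g K)`).
Users holding kinship-coefficient matrices must double them.

## Synthetic cohorts

The generator produces the structures the models assume, not realistic
mass-spectrometry data (no batch effects, no intensity-dependent noise,
no peptide level). Consequences: passing tests demonstrate correctness
of the estimators under their own assumptions and calibrated behaviour
under correlated-predictor designs; they do not demonstrate robustness
to assay artefacts, which the upstream processing of a real study must
remove.

- **Pedigree**: families drawn i.i.d. from a size distribution on 1–5
  (defaults {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.07, 5: 0.03}); each family
  block is compound-symmetric with relatedness 0.5, giving a PSD
  block-diagonal `K` (eigenvalues of a size-s block:
  1 + (s−1)r and 1 − r).
- **Proteome**: each signal is
  `√h² · g + factor component + noise`, with `g ~ N(0, K)`,
  `h² = genetic_variance_fraction` (default 0.3), shared latent factors
  (default 15) inducing cross-signal correlation, and variance shares
  summing to 1. The within-sib-pair correlation of a signal is
  `h² × 0.5` by construction.
- **Outcomes**: `Y = X B + E` with sparse planted `B` and multivariate
  normal residual rows (configurable outcome correlation, default 0.4
  exchangeable in the demo), then column-standardized. Standardization
  shrinks a planted β by `1/√(1+Σβ²)` on its outcome — negligible at the
  planted sizes used, but accounted for where tests assert recovery.
- **Covariates**: age, sex (never missing), BMI, weekly alcohol,
  epigenetic smoking score, deprivation index, 11-category ordinal
  education (0–10), and self-report depression / diabetes / high blood
  pressure, masked missing completely at random at per-column default
  rates (9/6/3/5/2/2/2/1%). The missingness mechanism in the motivating
  cohort is uncharacterized; MCAR is the assumption here, and entries
  are masked independently across covariates.
- **APOE ε4**: allele counts binomial(2, 0.15) (Hardy–Weinberg);
  designated signals shift additively per copy.
- **Survival**: onset ages follow a Weibull proportional-hazards model
  on the age scale (shape 4, mimicking steeply age-increasing dementia
  incidence; baseline scale 140 by default) with linear predictor
  `X·log_hr` over standardized signals plus an optional kinship-Gaussian
  log-frailty. Onset is drawn conditional on being event-free at study
  entry (participants are sampled alive). Censoring is administrative
  and independent of onset: follow-up ends at
  `entry + (1 − admin_censor_fraction) × max_follow_up` years (default
  17), capped at age 100 — so `admin_censor_fraction = 1` gives a
  zero-length window and no events.

## Preprocessing

Fixed order: inclusion rule → KNN imputation → inverse-rank normal
transform of signals → standardization.

- **Inverse-rank normal transform** uses the Blom offset:
  `Φ⁻¹((r − 3/8)/(m + 1/4))` over the m non-missing values, ties
  averaged; the offset is the common biobank convention, and for untied
  data the output is exactly a permutation of a fixed quantile grid.
- **Inclusion rule**: individuals need ≥ 40% of covariate columns
  measured (inclusive at the boundary; age and sex count in the
  denominator, so the default roster is a fixed 10-covariate
  denominator).
- **KNN imputation**: Gower distance over mutually observed covariates
  (absolute difference scaled by observed range for continuous/ordinal,
  0/1 mismatch for binary), k = 5, neighbour median for
  continuous/ordinal and mode for binary with the lower category on
  ties; observed cells are never altered. These match the defaults of
  the widely used R implementation of KNN imputation for mixed-type
  epidemiological tables.
- **Standardization** uses the sample SD (n−1); immaterial at cohort n
  but stated for exactness.

## Kinship linear mixed model

`y = Xb + g + e`, `g ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`, REML. One
spectral decomposition `K = U D Uᵀ` rotates the problem so the
covariance is diagonal in `δ = σ²_e/σ²_g`; the restricted likelihood is
profiled on an 81-point log-spaced grid over δ ∈ [1e−4, 1e4] refined by
bounded scalar minimization (tolerance 1e−8), with the OLS boundary
(σ²_g = 0) compared explicitly. The decomposition is cached and reused
across all signals of a scan — the only O(n³) step.

Residualization subtracts both the fixed effects and the BLUP of the
family effect (conditional residuals, shrinkage `d_i/(d_i+δ)` in the
rotated basis) and scales the result to mean 0, variance 1. Conditional
residuals remove family-shared signal; this matters because the joint
model downstream assumes exchangeable rows.

APOE ε4 enters as a 3-level factor (indicators for 1 and 2 copies
against 0), the protein as outcome; Wald z-tests per contrast. The basic
tier adjusts for age and sex; the full tier adds deprivation, BMI,
alcohol, smoking score, depression, education and high blood pressure.
Self-report diabetes is collected but ambiguous in the motivating
analysis's model roster, so it is excluded by default and available via
`include_diabetes`.

## Multivariate spike-and-slab joint regression

The core model: `Y (n×q) = X (n×p) B + E`, residual rows `~ N(0, Σ)`,

- exact point-mass spike: `β_jk | γ_jk ~ γ_jk N(0, τ²)`,
- indicators per (predictor, outcome) pair: `γ_jk ~ Bernoulli(π)`,
- `π ~ Beta(1, p)` (sparse a priori), `τ² ~ Inv-Gamma(0.01, 0.01)`
  (one slab scale shared by all coefficients),
- `Σ ~ Inv-Wishart(q + 2, I)`.

Gibbs sampling: each sweep visits all p·q coefficients in a freshly
randomized order, sampling γ from its Bernoulli full conditional with β
marginalized over spike vs slab — the sufficient statistics are
`b = (XᵀR₋)ⱼ· Ω·ₖ` and `A = (XᵀX)ⱼⱼ Ω_kk + 1/τ²` with `Ω = Σ⁻¹`
weighting residuals across outcomes — then β from `N(b/A, 1/A)` when
included. `XᵀR` is maintained by rank-one updates (O(p+q) per
coefficient) and refreshed exactly from `XᵀY − XᵀXB` once per iteration
to stop floating-point drift; Σ, τ², π follow by conjugate updates.
Defaults: 5 000 iterations, 1 000 burn-in. Inputs must be
pre-standardized; no intercepts are fitted.

Design choices that the source analysis leaves open, decided here:

- **Outcome-resolved indicators** (γ per predictor–outcome pair, not
  one per predictor): outcome-specific significance reporting requires
  inclusion resolved per outcome.
- **Model-averaged summaries**: posterior means and equal-tailed 95%
  credible intervals are computed over all retained draws with the
  spike's zeros included.
- **Significance conjunction**: PIP ≥ 0.95 *and* the credible interval
  excludes zero. Because the spike puts an exact atom at 0, the
  equal-tailed interval of a high-PIP coefficient often has an endpoint
  exactly 0 (the ≤5% zero draws sit in one tail); zero therefore counts
  as *included* only when strictly interior, and the degenerate [0, 0]
  interval is never significant. Any other reading makes the
  conjunction unsatisfiable between PIP 0.95 and 0.975.
- Convergence diagnostics (split-R̂/ESS via ArviZ) are reported for all
  coefficients with pooled PIP > 0.1 plus Σ diagonal, τ² and π;
  constant chains are flagged rather than fatal.

The sweep kernel is compiled with numba; all randomness is pre-drawn
per iteration from one `numpy` Generator, so a fixed seed reproduces
the draw stream bit for bit, and multiple chains use independently
spawned seeds.

## Kinship-frailty Cox model

Efron tie handling by default (Breslow by flag), exit age as the time
scale. The baseline fit is Newton–Raphson on the exact partial
likelihood derivatives (score-norm tolerance 1e−8, step-halving,
monotone-likelihood fits flagged as non-converged rather than raised).
Whether delayed entry should be modelled is left to the user: default
is risk from time 0 on the age scale, with left truncation at entry age
available (`use_entry`), matching the ambiguity in the motivating
analysis; the choice is recorded in the fit metadata.

The mixed model adds `b ~ N(0, σ²K)` on the linear predictor. For fixed
σ² the penalized partial likelihood is maximized jointly over (β, b) by
Newton, exploiting structure: the partial-likelihood Hessian in
linear-predictor space is `diag(w) − AAᵀ` with one column of A per
event (per Efron sub-term), and the penalty `(σ²K)⁻¹` is block-diagonal
across families, so each step uses batched small-block solves plus a
Woodbury correction and a D×D factorization (D = events) instead of
dense n×n algebra. σ² is then chosen by bounded maximization (tolerance
1e−6) of the Laplace approximation to the integrated partial likelihood
on [1e−6, 5]; σ² → 0 recovers the unpenalized fit. A kinship matrix
singular on the analysis subset receives a 1e−8 ridge with a warning.
The Laplace/penalized estimator of σ² carries the known downward bias
for log-normal frailty at moderate event counts — the recovery
benchmark documents estimates around 0.2–0.45 for a true 0.5 at ~400
events — while β is recovered essentially unbiased.

The dementia scan applies the ≥ 65 exit-age filter (inclusive) before
any fitting, standardizes each signal on the filtered subset, fits one
frailty-Cox model per signal (basic tier: age, sex; full tier adds the
covariate roster and APOE ε4 count as a numeric 0/1/2 covariate —
numeric for parsimony since the motivating analysis states no coding),
and attaches nominal (p < 0.05) and Bonferroni flags. A single signal's
failure is recorded in the output row, not fatal.

## Effective number of tests

PCA on the *correlation* matrix of the transformed signals (the signals
are rank-normalized to near-unit variance, so correlation vs covariance
nearly coincide; correlation is chosen for scale invariance). M is the
smallest component count whose cumulative eigenvalue share reaches 80%
(first crossing, inclusive); the family-wise threshold is the exact
quotient α/M, displayed at two significant figures.

## Pipeline

`run_all` executes simulate → preprocess → effective tests →
(residualize → joint model) × {basic, full} → APOE scan × 2 → dementia
scan × 2 → report, from one validated YAML config (unknown keys
rejected, ranges checked before any compute). Per-stage seeds derive
deterministically from the master seed via CRC-tagged `SeedSequence`s;
result TSVs contain no timestamps and are byte-identical across reruns
of the same config. The manifest records a config hash, per-stage
shapes, warnings and a SHA-256 per output file, and is written even on
failure with the failing stage recorded. The report prints significant
hits per analysis under the decision rules above plus the basic-vs-full
effect-size correlation as a diagnostic.

## Problem sizes

The bundled demo config runs ~710 individuals × 60 signals × 5 outcomes
end-to-end in about a minute. The calibration experiments in
`pwaskit.benchmarks` use: selection calibration n=1500, p=150, q=5, 12
planted effects of 0.15, 10 seeds; sib-pair REML recovery at 800 pairs;
Cox null calibration at 500 replicates of n=2000; frailty recovery at
20 replicates of 1500 sib pairs with baseline scale 120 (~400 events);
planted-HR recovery at n=5000 with baseline scale 146 (~250–300
events). These sizes make each check informative while keeping the
whole suite comfortably runnable on one CPU.

## Known limitations

- MCAR missingness and independent masking are assumptions, not
  cohort facts.
- The KNN imputer computes distances row-by-row against the full table
  (O(n²) worst case); adequate at tens of thousands of rows, not
  millions.
- The frailty σ² point estimate is downward-biased at modest event
  counts (see above); no standard error is reported for σ².
- One slab scale τ² is shared across all coefficients; effect-size
  heterogeneity across outcomes is absorbed by Σ, not by per-outcome
  slabs.
- The survival generator's administrative censoring is a deterministic
  follow-up window; it does not model competing mortality explicitly.
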