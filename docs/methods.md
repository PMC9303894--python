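# Methods

## The model

`panelnet` analyzes an n × p × 2 panel of ordinal symptom ratings (default:
the 22 IES-R items, responses 0–4, two waves a year apart) with two
complementary network models.

**Per-wave Gaussian graphical model.** Treating item scores as approximately
continuous, the wave's p × p Pearson correlation matrix R is fed to an
L1-penalized Gaussian likelihood,

    max_Θ  log det Θ − tr(R Θ) − λ Σ_{i≠j} |θ_ij| ,

solved by block coordinate descent over a descending path of `n_lambda`
(default 100) penalties from λ_max = max|off-diag R| (empty network) down to
`lambda_min_ratio`·λ_max (default 0.01), each point warm-started from the
previous. The selected model minimizes the extended BIC,
−2ℓ + E log n + 4γ E log p with E the number of nonzero edges and γ = 0.5 by
default; ties go to the sparser model, and entries below 1e−8 are treated as
exact zeros (solver noise floor). The precision estimate is reported on the
partial-correlation scale, w_ij = −θ_ij/√(θ_ii θ_jj). The solver is
implemented in numba because the permutation and bootstrap procedures
re-estimate the network tens of thousands of times; unit tests verify it
against an independent solver (scikit-learn's graphical lasso), against
closed-form inverses at λ = 0, and against the KKT stationarity conditions
along the path.

**Cross-lagged panel network.** Each wave-2 item is regressed on all p
wave-1 items with the lasso; the penalty is chosen per outcome by k-fold
cross-validation (default 10 folds, seeded random partition shared across
outcomes, CV-minimum rule; the conservative one-SE rule is available via
`one_se_rule=True`). Variables are standardized per wave before fitting so
coefficients are comparable across items — required for the expected
influence sums to be meaningful; a raw-scale flag exists. Squared-error loss
on the ordinal outcomes mirrors the continuous treatment of the items. The
coefficient matrix B has autoregressive paths on the diagonal; for display
the diagonal is zeroed and coefficients below the 0.05 threshold (boundary
kept: |b| ≥ 0.05 survives) are suppressed — display transforms never feed
back into centrality computation.

**Centralities.** Expected influence EI(i) = Σ_{j≠i} w_ij (one-step,
signed). For the CLPN, OEI(i) = Σ_{j≠i} B[i,j] and IEI(j) = Σ_{i≠j} B[i,j];
autoregressive paths are excluded by default because these are cross-lagged
centralities (exclusion also makes the order of zeroing and summation
irrelevant). z-scores standardize across the p nodes with the population SD,
the convention of centrality panel plots.

## Inference

**Network comparison test.** S = |GS_a − GS_b| where GS is the sum of
absolute edge weights over unique pairs ("overall connectivity"). Both
networks are re-estimated with the full glasso+EBIC pipeline for the
observed split and for each of `n_permutations` (default 1,000) random
re-partitions of the pooled participants into the original group sizes;
p = (1 + #{S_perm ≥ S_obs}) / (1 + n_permutations). Comparing baseline to
follow-up of the same participants treats the waves as independent groups —
faithful to common practice in two-wave applications; a paired variant that
permutes wave labels within participant is available (`paired=True`).

**Bootstraps.** Edge CIs are plain percentile intervals over replicates that
resample participants with replacement (default 1,000); failed replicates
are dropped and counted, with more than 5% failures aborting. Difference
tests flag a pair of edges (or centralities) when the (1−α) percentile
interval of the bootstrapped difference excludes zero; no multiplicity
correction, as in the bootstrap-stability framework this follows. The
case-drop bootstrap subsamples without replacement at drop proportions
{0.05, …, 0.75}, re-estimates, and correlates subset with full-sample
centralities; CS is the largest proportion at which ≥95% of replicates reach
r ≥ 0.7 (0 if none), with 0.50 the conventional strong-stability bar. Grid
points whose subsample falls below p are skipped with a warning. Every
replicate k draws from a generator seeded by (seed, k), so results are
independent of execution order.

## Data handling

Complete-case filtering spans both waves jointly (the analysis sample is
participants observed completely at both assessments). Predictive mean
matching runs as chained equations: columns visited left to right, each
incomplete column regressed (OLS) on all other columns of both waves using
currently-imputed values, and each missing cell given the observed value of
one of the 5 donors with the closest predicted means, for 5 sweeps.
Initialization draws randomly from the column's observed values. This is
the deterministic-prediction PMM variant (no posterior draw of the
regression parameters); with a single imputed dataset and the donor pool
absorbing most of the sampling noise, the distinction is immaterial for the
sensitivity-analysis use here. Only originally-missing cells are ever
modified, so runs with different seeds differ only there.

## The synthetic generator

The generator defines the study-like conditions every estimator is tested
under (`study_like_spec`): p = 22 items in five subscales (6 intrusion,
6 avoidance, 5 hyperarousal, 2 numbing, 3 sleep), n = 698, edge density
0.25 with within-subscale pairs 3× more likely, |partial correlations|
drawn from [0.1, 0.35] with 10% negative edges, autoregressive paths 0.4
plus 10 cross-lags in [0.15, 0.30].

Details worth knowing:

- **Positive definiteness** of the precision matrix is enforced by diagonal
  inflation (deterministic, no rejection sampling), which uniformly shrinks
  the realized partial correlations below their nominal range; all recovery
  scoring uses the realized truth recorded in the spec.
- **Stationary waves.** The wave-2 residual covariance is chosen as
  Σ_e = Σ₁ − BᵀΣ₁B so both waves share the same latent marginal — the two
  cross-sectional networks are estimates of one truth, matching the
  empirical finding that motivates comparing them.
- **Thresholds** per item place binomial(4, m/4) mass on the five
  categories, i.e. the cut points are normal quantiles of its cumulative
  probabilities; m is anchored to the published wave-1 item means
  (range 1.37–2.92), giving realistic unimodal Likert marginals.
- **Decline at follow-up.** A latent shift of 0.5 SD is subtracted at wave
  2. This reproduces a raw total-score decline of about half a scale point;
  the standardized effect (g ≈ −0.9) comes out larger than the empirical
  −0.49 because the synthetic inter-item correlations — and hence the
  total-score SD — are below those of the real instrument. Tests therefore
  score g against the generator's own latent oracle, not the published
  value.
- **Missingness** is a per-cell Bernoulli whose probability is a logistic
  function of the participant's standardized wave-1 latent total (slope 6,
  intercept calibrated exactly to the target rate). The steep slope
  concentrates missingness in a minority of low-scoring participants so
  that ~5% missing cells coexist with a large majority of fully complete
  rows, the joint pattern of the emulated design. The mechanism never looks
  at the masked cell's own value, making it MAR by construction with
  respect to the wave-1 total.

What the generator does not emulate: latent common causes, reverse-scored
items, measurement non-invariance across waves, panel attrition beyond the
MAR model, and between/within-person variance separation. Passing recovery
tests therefore show the estimators work under a faithful sparse-GGM world,
not that real IES-R data satisfy that world.

## Problem sizes and numerical choices

Resampling-heavy checks run at reduced but statistically meaningful sizes,
chosen as the package's own test conditions: the type-I-error calibration
uses 200 replications × 200 permutations with a 15-point penalty path
(n = 300 per group); recovery studies use 50 replicates at n = 698;
case-drop stability uses 100 subsamples per grid point. Coordinate descent
converges at tolerance 1e−4 on the working covariance (inner lasso at
1e−5); the λ = 0 path point is computed by direct inversion. Degenerate
inputs fail loudly: zero-variance items, fully-missing columns, empty
complete-case sets and sub-p subsamples all raise or warn by name.

## Known limitations

- Pearson correlations on 0–4 scores understate polychoric associations;
  the GGM accepts a precomputed correlation matrix for users who want to
  supply their own.
- The CV-minimum rule retains a few noise coefficients under a true-null
  CLPN (≈ 5–9% of entries); use `one_se_rule=True` when a conservative
  network matters more than power.
- McDonald's ω_t is not implemented (it requires a factor model);
  Cronbach's α is.
- Only the global-strength NCT sub-test is provided, not edge- or
  centrality-invariance sub-tests.
- Two waves only: contemporaneous/temporal decompositions need at least
  three time points and are out of scope.
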