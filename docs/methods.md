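# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `lpakit`. It is the place
where design decisions that were genuinely open are recorded.

## Measurement model

The latent profile model is a finite mixture of multivariate normals over
the p = 12 routinely collected indicators,
f(x) = Σ_k π_k N(x; μ_k, Σ_k), fitted by EM. Six covariance families
cross shape with across-profile constraints:

| family            | Σ_k                  | covariance parameters |
|-------------------|----------------------|-----------------------|
| spherical_equal   | σ²I, shared          | 1                     |
| spherical_varying | σ_k²I                | K                     |
| diagonal_equal    | diag(v), shared      | p                     |
| diagonal_varying  | diag(v_k)            | Kp                    |
| full_equal        | Σ, shared            | p(p+1)/2              |
| full_varying      | Σ_k                  | Kp(p+1)/2             |

The default family search is {diagonal_varying, full_varying} with BIC
arbitration, because count indicators live on wildly different scales and
profile-specific spread is the salient feature. Binary and ordinal
indicators (gender, ethnicity, diagnosis flag, deprivation decile) are
treated as numeric Gaussians, the conventional simplification in LPA of
mixed routine data; this is a deliberate misspecification and is one
reason fitted components should be read as data summaries, not as
literally Gaussian subpopulations.

Numerical choices:

* all densities in log space with log-sum-exp normalisation; posterior
  rows sum to 1 to 1e-10 by construction;
* covariance regularisation: eigenvalue (or variance) floor of
  1e-6 × the mean diagonal element. This is required because the
  generator's structural zeros make one indicator exactly constant within
  a profile; without a floor every K ≥ 2 likelihood is unbounded. When a
  floored M-step would decrease the observed-data log-likelihood (exact
  EM is monotone, floored EM need not be), the run stops and returns the
  best iterate, so recorded likelihood traces are always non-decreasing;
* initialisation: seeded k-means starts (default n_starts = 8 for
  standalone fits, 4 inside enumeration), plus warm starts; K = 1 is
  computed in closed form;
* convergence: relative log-likelihood change below tol (default 1e-8
  standalone, 1e-7 in enumeration); max_iter 1000 (300 in enumeration);
* label order: profiles are sorted ascending by the sum of their mean
  team-contact counts, so profile 1 is always the low-use profile;
* parameter counts d = (K−1) + Kp + (covariance parameters); AIC and BIC
  are reported in both conventions (2LL − penalty, "larger is better",
  used for selection; and −2LL + penalty). Normalised entropy is
  1 − Σ_i Σ_k(−τ_ik log τ_ik)/(n log K), defined as 1 when K = 1; the
  successive-K difference of this quantity is reported as the
  "normalised entropy difference". Mardia's multivariate skewness and
  kurtosis (ML covariance, divide-by-n) are computed as distributional
  diagnostics with their chi-square/normal test statistics.

## Profile enumeration

Stage 1 tests the 2- and 3-profile models against the one-class null;
stage 2 tests K+1 vs K upward from 2 while the test rejects at α = .05;
the selected model is the most parsimonious K not rejected in favour of
K+1. Two tests are computed:

* an adjusted likelihood-ratio test in the Lo–Mendell–Rubin spirit:
  2ΔLL divided by the Bartlett-style factor 1 + 1/(d log n), referred to
  χ²_d with d the difference in free parameters. The exact reference
  distribution at a mixture boundary is not chi-square, so this test is
  reported for comparability with common practice and is never the
  deciding input;
* the parametric bootstrapped LRT (BLRT): fit the null, simulate B
  datasets from it, refit both models to each replicate,
  p = (1 + #{boot ≥ observed})/(B + 1). B defaults to 99 for routine
  runs (999 is recommended for reported analyses). Replicate fits
  warm-start from the generating parameters (null) and a split of the
  refitted null (alternative) with slightly looser tolerances
  (rel. tol 2e-6, max 150 iterations, applied identically to both
  models of a replicate). This keeps B = 99 affordable at n ≈ 4000; the
  cost is a mildly liberal test (the observed statistic is computed from
  a stronger multi-start search than the replicates), measured at a
  type-I rate of 0.08 against a nominal .05 in the package's own
  200-replicate calibration experiment — inside the binomial 95% band.

The BLRT drives the stage decisions (2 vs 1 bootstrapped in stage 1,
every stage-2 rung bootstrapped); the 3-vs-1 stage-1 comparison uses the
plain nested chi-square LRT. When BIC and the LRT ladder disagree, the
LRT decision wins and the disagreement is logged in the decision trace.

## Synthetic cohort generator

The generator emulates the statistical structure of a routinely collected
service-receipt extract with two latent subgroups (mixing 0.7305/0.2695,
n = 3941 by default):

* count indicators (face-to-face, did-not-attend, and five team-contact
  counts) are negative binomial, moment-matched to the calibrated
  (mean, SD) cells: size r = m²/(s² − m) when s² > m, Poisson(m) when
  0 < s² ≤ m. The calibrated cells have SD ≫ mean (r ≈ 0.1–0.9), i.e.
  extreme right skew with a mode at zero — deliberately so, as that is
  what such service-use data look like;
* structural zeros: the low-use profile has exactly zero psychology
  contacts and no internalizing diagnoses (mean 0, SD 0; enforced
  exactly, not approximately);
* binaries (female 0.63, White 0.32, internalizing 120/1062 in the
  high-use profile) are Bernoulli; age is truncated normal on the
  [20, 101] inclusion window; deprivation decile is a discretised
  truncated normal on 1..10;
* within-profile count indicators are independent by default; an
  optional Gaussian-copula knob induces exchangeable correlation without
  changing the marginals;
* the repeated design ("T1+T2") draws two episode rows per patient with
  a shared profile and latent episode-to-episode correlation 0.5
  (a Gaussian copula over the count marginals); the published design
  comparison motivates having both, and 0.5 is a neutral middle value
  since no dependence was stated;
* an optional non-attendance model replaces the marginal did-not-attend
  cell by Poisson(b0_k + b1_k × nursing) with profile-specific
  coefficients (identity link by default so that a linear interaction
  model is correctly specified; a log link is available);
* determinism: every draw flows through one numpy Generator seeded from
  the config, so (config, seed) fully determines the cohort. The cohort
  CSV writer puts the generator's true labels in a sidecar file so that
  fitting code cannot read them by accident.

What the generator does **not** emulate: episode dates and lengths,
referral pathways, missingness (the emulated analytic sets are complete),
within-profile correlation structure of real caseloads, or any
profile-demographic dependence beyond the calibrated cells. Tests passing
on these cohorts therefore demonstrate correctness of the pipeline's
computations and its behaviour under a known two-subgroup truth — not
that real service data contain exactly two profiles.

## Structural model

Direct (1-step) effects are OLS regressions in both directions — each
engagement/team parameter on the 0/1 modal cluster (the between-profile
mean difference), and cluster on each parameter (with sociodemographic
rows reported in this direction, one single-predictor model per row).
Controlled (adapted 3-step) effects refit each model adding the E-step
posterior probability of the high-use profile, mean-centred, and its
product with the focal term; the focal coefficient is the controlled
effect. All-hard posteriors (exactly 0/1) make the covariate collinear
with modal class; such models are flagged degenerate rather than
estimated. Inference is t-based (B, SE, t, two-sided p, 95% CI) even for
count outcomes, matching how these general linear models are reported; a
log-link count alternative was considered and deliberately not made the
default. The nursing-by-cluster interaction on non-attendance is a
single OLS with product term, with fitted-rate curves exported on a
nursing grid per cluster. The Poisson goodness-of-fit check estimates
λ by the sample mean, merges count bins until every expected count is
≥ 5, and uses Pearson χ² with df = bins − 2.

## Resampling validation

Frame 1 is the whole sample (in-sample metrics); frame 2 a random 50/50
split; frame 3 ten independent seeded 80/20 holdouts (the literal
"5 parts, 10 folds" wording is ambiguous; re-randomised 80/20 splits
match the stated sizes and "train × test runs" reading, and a strict
5-fold × 2 mode is available behind the `mode="kfold"` flag). Odd n gives
the extra unit to the first half. The holdout classifier is an EDDA: one
Gaussian per class, all classes sharing one covariance family (the
"equal" families also share values — full_equal is LDA-like, full_varying
QDA-like), priors equal to training proportions, plug-in Bayes prediction
in log space. Metrics: classification error; Brier score (binary
convention (1/n)Σ(p_i − y_i)² on the high-use class for K = 2, a
multiclass (1/(nK)) generalisation otherwise); MAE/MAPE on 1..K integer
class codes; and MAE/MAPE of continuous engagement indicators predicted
by profile-conditional training means. Out-of-sample indices never
intersect their training set (asserted structurally). Split-half
congruence refits the mixture on each half, standardises each solution's
profile means by its own mixture-implied grand mean and SD, matches
profiles by the permutation maximising summed Tucker congruence, and
reports the mean matched congruence.

## Pipeline and seeds

`run_full_analysis` chains simulate → enumerate/select → describe →
structural → validate. Stage seeds derive from one root seed by
(root × 1000 + stage index) mod 2³¹−1, so any stage can be rerun in
isolation and full reruns are bit-identical. The structural and
validation stages are defined for the two-profile model; when selection
chooses a different K, those stages run on the enumerated 2-profile
solution and the log records this.

## Known limitations and observed behaviour

* **Over-extraction under skew.** Gaussian mixtures fitted to heavily
  overdispersed count data are known to add components that chase
  skewness rather than real subgroups (the classic non-normality
  pitfall in mixture enumeration). On cohorts from the default
  generator — whose negative-binomial marginals are extremely
  right-skewed by calibration — both BIC and the BLRT keep preferring
  larger K up to the K_max = 4 ladder cap, even though the generating
  truth has two subgroups. The acceptance checks compute and report
  exactly this behaviour. Practitioners applying the pipeline to such
  data should read the selected K together with the entropy, the
  split-half congruence and the profile-description table, not in
  isolation.
* **Modal-assignment share exceeds the generating weight.** Because the
  high-use profile's count marginals put much of their mass at zero, a
  few percent of high-use patients are genuinely indistinguishable from
  low-use ones; modal assignment sends them to the majority profile.
  The modal share of the larger profile on default cohorts is ≈ 76%,
  above the generating 73.05%, and the package's own exact-Bayes
  computation under the true generative law shows the same shift
  (≈ 75.8%) — it is a property of modal assignment under overlap, not an
  estimation error.
* The BLRT's warm-started replicate fitting is mildly liberal (see
  above); raise `replicate_starts` and `B` for confirmatory use.
* The adjusted (VLMR-style) LRT uses an approximate reference
  distribution; treat its p-values as descriptive.
* Problem sizes in the shipped tests and the acceptance script (n = 3941
  cohorts, 10 seeds, B = 99, 200-replicate calibration experiments) were
  chosen to keep a full run in the tens of minutes on one CPU while
  leaving every Monte-Carlo tolerance meaningful.
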