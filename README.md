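# lpakit

Latent profile analysis (LPA) of routinely collected mental-health
service-receipt data, with synthetic cohort generation, principled profile
enumeration, structural-model evaluation, and a protocolized resampling
validation scheme.

## The problem

Secondary mental-health services accumulate rich routine data — contacts
with clinical teams, missed appointments, demographics, diagnoses — but
individual patterns of engagement among patients with complex needs (such
as personality-disorder diagnoses) are poorly understood. LPA asks whether
a heterogeneous caseload decomposes into a small number of *profiles* of
service receipt (for example low-use vs high-use subgroups), whether those
profiles are statistically reliable, and whether routinely collected
indicators can predict profile membership well enough to inform care
planning.

Real extracts of this kind are governed patient data and cannot be
redistributed. `lpakit` therefore ships a seeded synthetic-cohort
generator whose defaults are calibrated to published per-profile summary
statistics from a large urban secondary-care cohort (n = 3941; a low-use
majority profile of 73.05% and a high-use minority profile with roughly
5–10× the contact counts), so the entire pipeline is testable end to end
without any data access.

## The model

Patients are described by p = 12 indicators
x_i = (age, female, White ethnicity, deprivation decile, internalizing
diagnosis, face-to-face contacts, did-not-attends, and contact counts for
medical, nursing, psychology, therapy and other teams). LPA is a finite
Gaussian mixture

  f(x_i) = Σ_{k=1..K} π_k N(x_i; μ_k, Σ_k),

with the E-step posterior τ_ik = π_k N(x_i; μ_k, Σ_k) / Σ_j π_j N(x_i; μ_j, Σ_j)
giving each patient's profile-membership probability and modal assignment
argmax_k τ_ik. Six covariance families are supported (spherical/diagonal/
full × equal/varying across profiles). The number of profiles is decided
by BIC enumeration plus two-stage likelihood-ratio testing: stage 1 tests
the 2- and 3-profile models against the one-class null; stage 2 tests
K+1 vs K upward while the parametric bootstrapped LRT (BLRT) rejects.
Structural evaluation relates indicators to membership by 1-step (direct)
and adapted 3-step (controlled) general linear models, the latter
conditioning on the E-step posterior. Validation uses three sampling
frames: the whole sample, a random 50/50 split (Tucker congruence of
profile structure), and ten 80/20 holdouts scored with an
eigenvalue-decomposition discriminant analysis (EDDA), Brier scores,
classification error and MAE/MAPE.

## Worked example

```python
from lpakit import cohort, mixture, validation

cfg = cohort.default_config()            # calibrated two-profile generator
df = cohort.generate_cohort(cfg, seed=1) # n=3941 patients, 12 indicators

order = [cohort.INDICATORS.index(c) for c in cohort.TEAM_INDICATORS]
sol = mixture.fit_mixture(df[cohort.INDICATORS], K=2,
                          family="diagonal_varying", seed=0, order_by=order)
fs = mixture.fit_statistics(sol)
print(f"loglik={sol.loglik:.1f}  BIC={fs.bic_mclust:.1f}  "
      f"entropy={fs.entropy_normalized:.3f}  "
      f"mean max posterior={fs.mean_max_posterior:.3f}")

frames = validation.make_frames(len(df), n_folds=10, seed=2)
rep = validation.cross_validate(df, sol.labels, frames,
                                family="diagonal_varying",
                                feature_cols=cohort.INDICATORS)
print(f"grand classification error={rep.grand['classification_error']:.4f}  "
      f"grand Brier={rep.grand['brier']:.4f}")
```

which prints

```
loglik=-69222.4  BIC=-138850.4  entropy=0.996  mean max posterior=0.999
grand classification error=0.0008  grand Brier=0.0005
```

Profile 1 is the low-use majority (structural zeros on psychology contacts
and internalizing diagnoses); profile 2 the high-use minority. The high
normalised entropy and mean maximum posterior (≫ 0.80) say assignment is
crisp; the near-zero out-of-sample error and Brier score say held-out
patients are classified into their profiles almost perfectly from the
routine indicators.

A command-line interface mirrors the stages:

```bash
lpakit simulate --seed 1 --out cohort.csv
lpakit select --data cohort.csv --kmax 4 --blrt-b 99 --seed 1 --out trace.json
lpakit run-all --seed 1 --out reports/
```

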