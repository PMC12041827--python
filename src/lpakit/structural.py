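"""Structural-model evaluation: relating indicators to profile membership.

After the measurement model (number of profiles) is fixed, the structural
question is how each routinely collected parameter relates to cluster
membership. Two procedures are provided:

* direct (1-step) effects — ordinary least squares of one variable on the
  other, in both directions: each engagement/team parameter regressed on
  modal cluster (the between-profile mean difference), and the 0/1 cluster
  indicator regressed on each parameter;
* controlled (adapted 3-step) effects — the same models refitted with the
  patient-level posterior probability of the high-use profile (from the
  E-step of the measurement model), mean-centred, and its product with the
  focal predictor added as covariates. The focal term's coefficient is the
  controlled effect: the association that remains once assignment
  certainty is conditioned on.

Inference is t-based throughout (B, SE, t, two-sided p, 95% CI), matching
how such general linear models are conventionally reported even for count
outcomes; a Pearson chi-square goodness-of-fit check against a Poisson law
is provided for count outcomes such as missed appointments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ENGAGEMENT_PARAMS = ["dna", "f2f"]
TEAM_PARAMS = ["medical", "nurse", "psychology", "therapy", "other"]
SOCIODEMOGRAPHIC_PARAMS = ["internalizing", "white", "female"]


@dataclass
class EffectEstimate:
    """One regression path: focal slope with t-based inference."""

    outcome: str
    predictor: str
    B: float
    ci_low: float
    ci_high: float
    t: float
    df_resid: int
    p_value: float
    kind: str  # "direct" or "controlled"
    covariates: tuple[str, ...] = ()
    degenerate: bool = False
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "B": self.B,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t": self.t,
            "df_resid": self.df_resid,
            "p_value": self.p_value,
            "kind": self.kind,
            "covariates": list(self.covariates),
            "degenerate": self.degenerate,
            "note": self.note,
        }


def _degenerate(outcome, predictor, kind, covariates, note) -> EffectEstimate:
    return EffectEstimate(
        outcome=outcome,
        predictor=predictor,
        B=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        t=np.nan,
        df_resid=0,
        p_value=np.nan,
        kind=kind,
        covariates=tuple(covariates),
        degenerate=True,
        note=note,
    )


def linear_effect(
    y,
    x,
    covariates=None,
    outcome: str = "y",
    predictor: str = "x",
    covariate_names: tuple[str, ...] = (),
    kind: str = "direct",
) -> EffectEstimate:
    """OLS of y on x (plus optional covariates) with intercept.

    Reports the focal predictor's slope B, its 95% CI (B +/- t_{.975,df}SE),
    t statistic and two-sided p. Perfect collinearity in the design is
    flagged and the effect reported as degenerate rather than silently
    dropped.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("y and x must have equal length")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
        cols.extend(C.T)
    Xmat = np.column_stack(cols)
    n, k = Xmat.shape
    if n <= k:
        raise ValueError("need n > number of predictors + 1")
    if np.linalg.matrix_rank(Xmat) < k:
        return _degenerate(
            outcome, predictor, kind, covariate_names,
            "design matrix is rank deficient (perfect collinearity)",
        )
    fit = sm.OLS(y, Xmat).fit()
    B = float(fit.params[1])
    se = float(fit.bse[1])
    df = int(fit.df_resid)
    tval = B / se if se > 0 else np.inf * np.sign(B)
    crit = stats.t.ppf(0.975, df)
    p = float(2.0 * stats.t.sf(abs(tval), df)) if np.isfinite(tval) else 0.0
    return EffectEstimate(
        outcome=outcome,
        predictor=predictor,
        B=B,
        ci_low=B - crit * se,
        ci_high=B + crit * se,
        t=float(tval),
        df_resid=df,
        p_value=p,
        kind=kind,
        covariates=tuple(covariate_names),
    )


def effects_table(effects: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])


def _modal_binary(solution) -> np.ndarray:
    """0/1 coding of modal class (0 = low-use profile)."""
    if solution.K != 2:
        raise ValueError("structural evaluation is defined for the 2-profile case")
    return (solution.labels == 1).astype(float)


def direct_effects(solution, data: pd.DataFrame) -> list[EffectEstimate]:
    """Unadjusted 1-step effects in both directions, one model per parameter.

    Direction 1: parameter ~ cluster (B is the high-minus-low mean
    difference). Direction 2: cluster ~ parameter, including the
    sociodemographic covariates (internalizing, ethnicity, gender) in this
    direction only. A constant cluster vector (K=1) flags every effect
    degenerate.
    """
    effects: list[EffectEstimate] = []
    if solution.K < 2 or len(np.unique(solution.labels)) < 2:
        for param in ENGAGEMENT_PARAMS + TEAM_PARAMS:
            effects.append(
                _degenerate(param, "cluster", "direct", (), "cluster vector is constant")
            )
        return effects
    cluster = _modal_binary(solution)
    for param in ENGAGEMENT_PARAMS + TEAM_PARAMS:
        effects.append(
            linear_effect(
                data[param].values, cluster, outcome=param, predictor="cluster"
            )
        )
    for param in ENGAGEMENT_PARAMS + TEAM_PARAMS + SOCIODEMOGRAPHIC_PARAMS:
        effects.append(
            linear_effect(
                cluster, data[param].values, outcome="cluster", predictor=param
            )
        )
    return effects


def controlled_effects(
    solution, data: pd.DataFrame, hard_tol: float = 1e-12
) -> list[EffectEstimate]:
    """Adapted 3-step effects conditioning on assignment probability.

    Step 1 is the enumeration done upstream; step 2 extracts each patient's
    posterior probability of the high-use profile from the E-step; step 3
    refits every direct-effect model with that probability (mean-centred)
    and its product with the focal term added as covariates. When the
    posteriors are all exactly 0/1 the probability is collinear with modal
    class and the effects are reported degenerate rather than estimated.
    """
    if solution.K != 2:
        raise ValueError("the 3-step procedure is implemented for K = 2")
    p2 = solution.tau[:, 1]
    hard = bool(np.all((p2 < hard_tol) | (p2 > 1 - hard_tol)))
    cluster = _modal_binary(solution)
    pc = p2 - p2.mean()
    effects: list[EffectEstimate] = []
    for param in ENGAGEMENT_PARAMS + TEAM_PARAMS:
        if hard:
            effects.append(
                _degenerate(
                    param, "cluster", "controlled", ("posterior", "posterior:cluster"),
                    "posteriors are all hard 0/1; probability is collinear with modal class",
                )
            )
            continue
        cov = np.column_stack([pc, pc * cluster])
        effects.append(
            linear_effect(
                data[param].values,
                cluster,
                covariates=cov,
                outcome=param,
                predictor="cluster",
                covariate_names=("posterior", "posterior:cluster"),
                kind="controlled",
            )
        )
    for param in ENGAGEMENT_PARAMS + TEAM_PARAMS:
        x = data[param].values.astype(float)
        if hard:
            effects.append(
                _degenerate(
                    "cluster", param, "controlled", ("posterior", f"posterior:{param}"),
                    "posteriors are all hard 0/1; probability is collinear with modal class",
                )
            )
            continue
        cov = np.column_stack([pc, pc * x])
        effects.append(
            linear_effect(
                cluster,
                x,
                covariates=cov,
                outcome="cluster",
                predictor=param,
                covariate_names=("posterior", f"posterior:{param}"),
                kind="controlled",
            )
        )
    return effects


@dataclass
class InteractionResult:
    """dna ~ nurse * cluster linear model plus fitted-rate curves."""

    effects: list[EffectEstimate]
    fitted_curves: pd.DataFrame

    def interaction(self) -> EffectEstimate:
        return next(e for e in self.effects if e.predictor == "nurse:cluster")


def interaction_model(dna, nurse, cluster) -> InteractionResult:
    """Nursing-by-cluster interaction on non-attendance.

    Fits dna ~ nurse + cluster + nurse:cluster by OLS with t inference and
    exports fitted non-attendance rates over a nursing-contact grid for
    each cluster (for plotting).
    """
    dna = np.asarray(dna, dtype=float)
    nurse = np.asarray(nurse, dtype=float)
    cluster = np.asarray(cluster, dtype=float)
    if not (len(dna) == len(nurse) == len(cluster)):
        raise ValueError("dna, nurse and cluster must have equal length")
    if len(np.unique(cluster)) != 2:
        raise ValueError("exactly two clusters are required")
    cluster01 = (cluster == np.max(cluster)).astype(float)
    X = np.column_stack([np.ones_like(dna), nurse, cluster01, nurse * cluster01])
    names = ["intercept", "nurse", "cluster", "nurse:cluster"]
    fit = sm.OLS(dna, X).fit()
    df = int(fit.df_resid)
    crit = stats.t.ppf(0.975, df)
    effects = []
    for j, name in enumerate(names[1:], start=1):
        B = float(fit.params[j])
        se = float(fit.bse[j])
        tval = B / se if se > 0 else np.inf
        effects.append(
            EffectEstimate(
                outcome="dna",
                predictor=name,
                B=B,
                ci_low=B - crit * se,
                ci_high=B + crit * se,
                t=float(tval),
                df_resid=df,
                p_value=float(2.0 * stats.t.sf(abs(tval), df)),
                kind="direct",
                covariates=tuple(n for n in names[1:] if n != name),
            )
        )
    grid = np.linspace(0.0, float(np.quantile(nurse, 0.99)), 50)
    rows = []
    for c in (0.0, 1.0):
        fitted = (
            fit.params[0]
            + fit.params[1] * grid
            + fit.params[2] * c
            + fit.params[3] * grid * c
        )
        rows.append(
            pd.DataFrame({"nurse": grid, "cluster": int(c), "fitted_dna": fitted})
        )
    return InteractionResult(
        effects=effects, fitted_curves=pd.concat(rows, ignore_index=True)
    )


@dataclass
class GofResult:
    """Pearson chi-square goodness of fit of counts to a Poisson law."""

    statistic: float
    df: int
    p_value: float
    bin_edges: list
    observed: list
    expected: list
    lambda_hat: float
    degenerate: bool = False
    note: str | None = None


def poisson_gof(counts, min_expected: float = 5.0) -> GofResult:
    """Test whether counts are consistent with a Poisson distribution.

    The rate is estimated by the sample mean; expected bin counts come from
    Poisson(lambda-hat) over 0, 1, 2, ... with cells merged (accumulating
    towards the right tail) until every expected count is at least
    ``min_expected``. The Pearson chi-square has df = (number of merged
    bins) - 2: one constraint for the total and one for the estimated rate.
    """
    counts = np.asarray(counts)
    if counts.size < 30:
        raise ValueError("need at least 30 observations")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.all(counts == counts[0]):
        return GofResult(
            statistic=np.nan, df=0, p_value=np.nan, bin_edges=[], observed=[],
            expected=[], lambda_hat=float(counts[0]), degenerate=True,
            note="all counts equal; no dispersion to test",
        )
    n = counts.size
    lam = float(counts.mean())
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(ks, lam)
    tail = float(stats.poisson.sf(kmax, lam))
    probs = np.append(pmf, tail)  # last cell is "> kmax"
    obs = np.append(np.bincount(counts.astype(int), minlength=kmax + 1), 0)
    exp = probs * n

    out_o: list[float] = []
    out_e: list[float] = []
    edges: list[int] = []
    acc_o, acc_e = 0.0, 0.0
    for i in range(len(exp)):
        acc_o += obs[i]
        acc_e += exp[i]
        if acc_e >= min_expected:
            out_o.append(acc_o)
            out_e.append(acc_e)
            edges.append(i)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0 or acc_o > 0:  # leftover right tail below threshold
        if out_e:
            out_o[-1] += acc_o
            out_e[-1] += acc_e
        else:
            out_o.append(acc_o)
            out_e.append(acc_e)
            edges.append(len(exp) - 1)
    merged_obs = np.asarray(out_o)
    merged_exp = np.asarray(out_e)
    nbins = len(merged_obs)
    df = nbins - 2
    statistic = float(np.sum((merged_obs - merged_exp) ** 2 / merged_exp))
    if df <= 0:
        return GofResult(
            statistic=statistic, df=df, p_value=np.nan, bin_edges=edges,
            observed=merged_obs.tolist(), expected=merged_exp.tolist(),
            lambda_hat=lam, degenerate=True, note="too few bins after merging",
        )
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        bin_edges=edges,
        observed=merged_obs.tolist(),
        expected=merged_exp.tolist(),
        lambda_hat=lam,
    )
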