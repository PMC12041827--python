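"""Profile enumeration and two-stage likelihood-ratio model selection.

The number of latent profiles K is decided by the procedure used in applied
latent-profile work: candidate solutions are enumerated over K and
covariance family and compared on BIC, and the profile count is then tested
with likelihood-ratio comparisons of the K-profile model against the
(K-1)-profile model — an analytically adjusted test in the spirit of
Lo-Mendell-Rubin, and a parametric bootstrapped LRT (BLRT), which is the
authoritative decision input here because the regularity conditions behind
chi-square references fail at a mixture boundary.

Stage 1 tests the 2- and 3-profile solutions against the one-class null;
stage 2 tests K+1 vs K upward from 2 while the BLRT keeps rejecting. The
selected model is the most parsimonious K not rejected in favour of K+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import (
    FitStatistics,
    MixtureParams,
    ProfileSolution,
    fit_mixture,
    fit_statistics,
    sample_from_params,
)

DEFAULT_FAMILIES = ("diagonal_varying", "full_varying")


@dataclass
class LRTResult:
    """A K vs K-1 (or K vs 1) likelihood-ratio comparison."""

    null_K: int
    alt_K: int
    statistic: float
    p_value: float
    kind: str  # "vlmr" or "bootstrapped"
    df: int | None = None
    adjusted_statistic: float | None = None
    B: int | None = None
    seed: int | None = None
    n_failed: int = 0
    boot_statistics: np.ndarray | None = None
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "null_K": self.null_K,
            "alt_K": self.alt_K,
            "statistic": self.statistic,
            "adjusted_statistic": self.adjusted_statistic,
            "p_value": self.p_value,
            "kind": self.kind,
            "df": self.df,
            "B": self.B,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "warning": self.warning,
        }


@dataclass
class EnumerationResult:
    """All fitted (K, family) candidates with fit statistics."""

    solutions: dict[tuple[int, str], ProfileSolution]
    statistics: dict[tuple[int, str], FitStatistics]
    failures: dict[tuple[int, str], str]
    best: tuple[int, str]

    def table(self) -> pd.DataFrame:
        rows = []
        for (K, fam), fs in self.statistics.items():
            rows.append(
                {
                    "K": K,
                    "family": fam,
                    "loglik": fs.loglik,
                    "n_parameters": fs.n_parameters,
                    "aic": fs.aic,
                    "bic_mclust": fs.bic_mclust,
                    "bic": fs.bic,
                    "entropy_normalized": fs.entropy_normalized,
                    "mean_max_posterior": fs.mean_max_posterior,
                    "best": (K, fam) == self.best,
                }
            )
        return pd.DataFrame(rows).sort_values(["family", "K"], ignore_index=True)


def enumerate_solutions(
    data,
    K_range=(1, 2, 3, 4),
    families=DEFAULT_FAMILIES,
    seed: int = 0,
    order_by=None,
    **fit_kwargs,
) -> EnumerationResult:
    """Fit every K x family candidate; the BIC-best cell is flagged.

    "Best" maximises 2*LL - d*log(n) (the model-based-clustering BIC
    convention). A failing cell is recorded, not fatal.
    """
    K_range = sorted(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    X = np.asarray(getattr(data, "values", data), dtype=float)
    if max(K_range) >= X.shape[0]:
        raise ValueError("max(K_range) must be < n")
    solutions: dict[tuple[int, str], ProfileSolution] = {}
    statistics: dict[tuple[int, str], FitStatistics] = {}
    failures: dict[tuple[int, str], str] = {}
    for fam in families:
        prev: ProfileSolution | None = None
        for K in K_range:
            try:
                warm = _split_init(X, prev) if (prev is not None and K == prev.K + 1) else None
                sol = fit_mixture(
                    X, K, family=fam, seed=seed, order_by=order_by,
                    init_params=warm, **fit_kwargs,
                )
            except Exception as exc:  # noqa: BLE001 - recorded per cell
                failures[(K, fam)] = f"{type(exc).__name__}: {exc}"
                continue
            solutions[(K, fam)] = sol
            statistics[(K, fam)] = fit_statistics(sol)
            prev = sol
    if not statistics:
        raise RuntimeError("every enumeration cell failed")
    best = max(statistics, key=lambda key: statistics[key].bic_mclust)
    return EnumerationResult(solutions, statistics, failures, best)


def _split_init(X: np.ndarray, sol: ProfileSolution, target_K: int | None = None) -> MixtureParams:
    """Warm start for a larger model: split heaviest components of a solution.

    Guarantees (up to EM convergence) that the larger model's likelihood is
    at least the smaller model's, which keeps 2*dLL >= 0 in nested tests.
    Splitting repeats until ``target_K`` components (default K+1).
    """
    params = _split_params(sol.params)
    target_K = params.K if target_K is None else target_K
    while params.K < target_K:
        params = _split_params(params)
    return params


def _split_params(p: MixtureParams) -> MixtureParams:
    k = int(np.argmax(p.weights))
    means = p.means.copy()
    cov = p.full_covariances()[k]
    direction = np.sqrt(np.maximum(np.diag(cov), 0.0))
    new_means = np.vstack([means, means[k] + 0.5 * direction])
    means[k] = means[k] - 0.5 * direction
    new_means[k] = means[k]
    w = p.weights.copy()
    new_w = np.append(w, w[k] / 2.0)
    new_w[k] = w[k] / 2.0
    cv = p.covariances
    if p.family.startswith("spherical"):
        new_cov = np.append(cv, cv[k])
    elif p.family.startswith("diagonal"):
        new_cov = np.vstack([cv, cv[k][None, :]])
    else:
        new_cov = np.concatenate([cv, cv[k][None, :, :]], axis=0)
    return MixtureParams(
        K=p.K + 1,
        p=p.p,
        weights=new_w / new_w.sum(),
        means=new_means,
        covariances=new_cov,
        family=p.family,
    )


def vlmr_lrt(
    null_solution: ProfileSolution, alt_solution: ProfileSolution, n: int | None = None
) -> LRTResult:
    """Adjusted likelihood-ratio comparison of K vs K-1 profiles.

    The statistic is 2*(LL_alt - LL_null), floored at zero (a negative
    value flags a suspected local optimum in the larger model). The
    adjustment applied is the Bartlett-style correction proposed by
    Lo, Mendell and Rubin: statistic / (1 + 1/(d * log n)) with d the
    difference in free parameters, referred to a chi-square with d degrees
    of freedom. Chi-square references at a mixture boundary are approximate
    at best; the bootstrapped LRT is the authoritative test and this one is
    reported for comparability with common practice.
    """
    if alt_solution.K != null_solution.K + 1:
        raise ValueError("vlmr_lrt compares K against K-1")
    n = null_solution.n if n is None else n
    raw = 2.0 * (alt_solution.loglik - null_solution.loglik)
    warning = None
    if raw < 0:
        warning = "alternative log-likelihood below null; local optimum suspected"
        raw = 0.0
    d = alt_solution.n_parameters - null_solution.n_parameters
    adj = raw / (1.0 + 1.0 / (d * np.log(n)))
    p = float(stats.chi2.sf(adj, d)) if raw > 0 else 1.0
    return LRTResult(
        null_K=null_solution.K,
        alt_K=alt_solution.K,
        statistic=float(raw),
        adjusted_statistic=float(adj),
        p_value=p,
        kind="vlmr",
        df=d,
        warning=warning,
    )


def _nested_lrt(
    null_solution: ProfileSolution, alt_solution: ProfileSolution
) -> LRTResult:
    """Plain nested LRT (chi-square reference) for non-adjacent K comparisons."""
    raw = 2.0 * (alt_solution.loglik - null_solution.loglik)
    warning = None
    if raw < 0:
        warning = "alternative log-likelihood below null; local optimum suspected"
        raw = 0.0
    d = alt_solution.n_parameters - null_solution.n_parameters
    p = float(stats.chi2.sf(raw, d)) if raw > 0 else 1.0
    return LRTResult(
        null_K=null_solution.K,
        alt_K=alt_solution.K,
        statistic=float(raw),
        p_value=p,
        kind="vlmr",
        df=d,
        warning=warning,
    )


def bootstrap_lrt(
    data,
    alt_K: int,
    family: str = "diagonal_varying",
    B: int = 99,
    seed: int = 0,
    null_K: int | None = None,
    null_solution: ProfileSolution | None = None,
    alt_solution: ProfileSolution | None = None,
    n_starts: int = 4,
    replicate_starts: int = 0,
    tol: float = 1e-7,
    max_iter: int = 300,
    replicate_tol: float | None = None,
    replicate_max_iter: int | None = None,
    max_failure_frac: float = 0.10,
) -> LRTResult:
    """Parametric bootstrapped LRT of alt_K profiles against null_K.

    The null model (default alt_K - 1 profiles) is fitted to the data, B
    datasets of the same size are simulated from it, both models are
    refitted to each replicate, and the p-value is
    (1 + #{bootstrap statistics >= observed}) / (B + 1). Deterministic
    given seed.

    Replicate fits warm-start from the generating parameters (null model)
    and from a split of the refitted null (alternative), plus
    ``replicate_starts`` extra k-means starts (0 by default: on data
    simulated from the null, the generating parameters are an excellent
    start, and skipping the k-means search keeps B=99 affordable).
    ``replicate_tol``/``replicate_max_iter`` loosen the replicate EM
    (defaults: max(tol, 2e-6) and min(max_iter, 150)); the same truncation
    applies to the null and alternative fit of each replicate, so the
    bootstrap statistics remain internally comparable.
    """
    if B < 19:
        raise ValueError("B must be at least 19")
    if alt_K < 2:
        raise ValueError("alt_K must be >= 2")
    null_K = alt_K - 1 if null_K is None else null_K
    if not 1 <= null_K < alt_K:
        raise ValueError("need 1 <= null_K < alt_K")
    X = np.asarray(getattr(data, "values", data), dtype=float)
    n = X.shape[0]

    if null_solution is None:
        null_solution = fit_mixture(
            X, null_K, family=family, n_starts=n_starts, seed=seed, tol=tol,
            max_iter=max_iter,
        )
    if alt_solution is None:
        alt_solution = fit_mixture(
            X, alt_K, family=family, n_starts=n_starts, seed=seed, tol=tol,
            max_iter=max_iter,
            init_params=_split_init(X, null_solution, target_K=alt_K),
        )
    observed = max(0.0, 2.0 * (alt_solution.loglik - null_solution.loglik))

    rep_tol = max(tol, 2e-6) if replicate_tol is None else replicate_tol
    rep_max_iter = min(max_iter, 150) if replicate_max_iter is None else replicate_max_iter
    ss = np.random.SeedSequence(seed)
    boot_stats = []
    n_failed = 0
    for child in ss.spawn(B):
        rng = np.random.default_rng(child)
        fit_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        Xb = sample_from_params(null_solution.params, n, rng)
        try:
            sol0 = fit_mixture(
                Xb, null_K, family=family, n_starts=replicate_starts, seed=fit_seed,
                tol=rep_tol, max_iter=rep_max_iter, init_params=null_solution.params,
            )
            sol1 = fit_mixture(
                Xb, alt_K, family=family, n_starts=replicate_starts, seed=fit_seed,
                tol=rep_tol, max_iter=rep_max_iter,
                init_params=_split_init(Xb, sol0, target_K=alt_K),
            )
        except Exception:  # noqa: BLE001 - replicate failures are counted
            n_failed += 1
            continue
        boot_stats.append(max(0.0, 2.0 * (sol1.loglik - sol0.loglik)))
    if n_failed > max_failure_frac * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed to fit")
    boot_stats = np.asarray(boot_stats)
    p = (1.0 + float(np.sum(boot_stats >= observed))) / (len(boot_stats) + 1.0)
    return LRTResult(
        null_K=null_K,
        alt_K=alt_K,
        statistic=float(observed),
        p_value=float(p),
        kind="bootstrapped",
        B=B,
        seed=seed,
        n_failed=n_failed,
        boot_statistics=boot_stats,
    )


@dataclass
class SelectionTrace:
    """Complete record of a two-stage selection decision."""

    enumeration: EnumerationResult
    family: str
    stage1: list[LRTResult] = field(default_factory=list)
    stage2: list[LRTResult] = field(default_factory=list)
    selected_K: int = 1
    bic_best_K: int = 1
    bic_lrt_disagreement: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "selected_K": self.selected_K,
            "bic_best_K": self.bic_best_K,
            "bic_lrt_disagreement": self.bic_lrt_disagreement,
            "stage1": [r.to_dict() for r in self.stage1],
            "stage2": [r.to_dict() for r in self.stage2],
            "enumeration": self.table_records(),
            "notes": list(self.notes),
        }

    def table_records(self) -> list[dict]:
        return self.enumeration.table().to_dict(orient="records")


def two_stage_selection(
    data,
    families=DEFAULT_FAMILIES,
    seed: int = 0,
    K_max: int = 4,
    B: int = 99,
    alpha: float = 0.05,
    order_by=None,
    n_starts: int = 4,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> tuple[ProfileSolution, SelectionTrace]:
    """Decide the number of profiles by BIC enumeration plus two-stage LRTs.

    Stage 1 tests the 2- and 3-profile models against the one-class null:
    the adjusted (VLMR-style) test for both comparisons, and the
    bootstrapped LRT for 2 vs 1 — the comparison the applied protocol
    bootstraps — with the BLRT authoritative for the 2-vs-1 decision. If
    stage 1 never rejects, the one-class model is selected. Stage 2 then
    tests K+1 vs K upward from K=2 with the BLRT while it rejects at
    ``alpha``; the selected model is the most parsimonious K not rejected
    in favour of K+1. The covariance family is arbitrated by BIC across
    the enumeration grid; if the BIC-best K disagrees with the LRT
    decision, the LRT wins and the disagreement is recorded in the trace.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    if X.shape[0] < 50:
        raise ValueError("two_stage_selection requires n >= 50")
    enum = enumerate_solutions(
        X, K_range=range(1, K_max + 1), families=families, seed=seed,
        order_by=order_by, n_starts=n_starts, tol=tol, max_iter=max_iter,
    )
    family = enum.best[1]
    trace = SelectionTrace(enumeration=enum, family=family, bic_best_K=enum.best[0])

    def _boot(null_K: int, alt_K: int) -> LRTResult:
        return bootstrap_lrt(
            X, alt_K, family=family, B=B, seed=seed + 97 * alt_K + null_K,
            null_K=null_K,
            null_solution=enum.solutions.get((null_K, family)),
            alt_solution=enum.solutions.get((alt_K, family)),
            tol=tol, max_iter=max_iter,
        )

    # stage 1: 2 vs 1 (VLMR + BLRT) and 3 vs 1 (nested LRT, chi-square ref)
    sols = enum.solutions
    if (2, family) in sols:
        trace.stage1.append(vlmr_lrt(sols[(1, family)], sols[(2, family)]))
        trace.stage1.append(_boot(1, 2))
    if (3, family) in sols:
        trace.stage1.append(_nested_lrt(sols[(1, family)], sols[(3, family)]))
    stage1_reject = any(r.p_value <= alpha for r in trace.stage1)
    if not stage1_reject:
        trace.selected_K = 1
    else:
        K = 2
        while K < K_max and (K + 1, family) in enum.solutions:
            res = _boot(K, K + 1)
            trace.stage2.append(res)
            if res.p_value > alpha:
                break
            K += 1
        trace.selected_K = K
        if K == K_max:
            trace.notes.append(
                f"selection reached K_max={K_max}; larger models were not tested"
            )

    if trace.selected_K != trace.bic_best_K:
        trace.bic_lrt_disagreement = True
        trace.notes.append(
            f"BIC prefers K={trace.bic_best_K} but the LRT decision "
            f"selects K={trace.selected_K}; the LRT decision wins"
        )
    selected = enum.solutions[(trace.selected_K, family)]
    return selected, trace
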