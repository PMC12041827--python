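"""Three-frame resampling validation of a latent profile solution.

The protocol assesses whether a fitted profile structure is a reproducible
property of the population rather than an artefact of one sample:

* frame 1 — the whole sample: in-sample classification error and Brier
  score of a discriminant model refitted to the modal assignment;
* frame 2 — a random 50/50 split: the mixture is refitted on each half and
  the matched Tucker congruence of standardised profile-mean vectors
  measures structural agreement;
* frame 3 — ten 80/20 train/test holdouts: an eigenvalue-decomposition
  discriminant analysis (EDDA; one Gaussian per class, every class sharing
  one covariance family, with "equal" families additionally sharing the
  covariance values) is trained on each training part and scored out of
  sample by classification error, Brier score, and MAE/MAPE.

The Brier score here is the mean squared difference between the predicted
probability of the high-use class and its indicator (0 best, 1 worst);
MAE/MAPE are computed on 1..K integer class codes, and MAE additionally on
continuous engagement indicators predicted by profile-conditional training
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .mixture import (
    FAMILIES,
    MixtureParams,
    ProfileSolution,
    _log_resp,
    _m_step,
)

# ---------------------------------------------------------------------------
# sampling frames


@dataclass
class SampleFrames:
    """Frame 1 (all), frame 2 (two halves) and frame 3 (holdout folds)."""

    n: int
    frame1: np.ndarray
    frame2: tuple[np.ndarray, np.ndarray]
    frame3: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    mode: str = "repeated_holdout"


def make_frames(
    n: int,
    n_folds: int = 10,
    seed: int = 0,
    test_frac: float = 0.2,
    mode: str = "repeated_holdout",
) -> SampleFrames:
    """Build the three sampling frames, deterministically from the seed.

    Frame 2 splits a random permutation into two halves (odd n gives the
    extra unit to half a). Frame 3 is, by default, ``n_folds`` independent
    seeded 80/20 splits, re-randomised each fold; ``mode="kfold"`` instead
    uses strict 5-fold partitions repeated ``n_folds // 5`` times.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    root = np.random.SeedSequence(seed)
    frame1 = np.arange(n)
    rng = np.random.default_rng(root.spawn(1)[0])
    perm = rng.permutation(n)
    half = (n + 1) // 2
    frame2 = (np.sort(perm[:half]), np.sort(perm[half:]))
    n_test = int(round(n * test_frac))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if mode == "repeated_holdout":
        for child in root.spawn(n_folds + 1)[1:]:
            p = np.random.default_rng(child).permutation(n)
            folds.append((np.sort(p[n_test:]), np.sort(p[:n_test])))
    elif mode == "kfold":
        k = int(round(1.0 / test_frac))
        repeats = max(1, n_folds // k)
        for child in root.spawn(repeats + 1)[1:]:
            p = np.random.default_rng(child).permutation(n)
            for part in np.array_split(p, k):
                test = np.sort(part)
                folds.append((np.sort(np.setdiff1d(p, part)), test))
    else:
        raise ValueError("mode must be 'repeated_holdout' or 'kfold'")
    return SampleFrames(n=n, frame1=frame1, frame2=frame2, frame3=folds, seed=seed, mode=mode)


# ---------------------------------------------------------------------------
# EDDA classifier


@dataclass
class EDDAClassifier:
    """Supervised Gaussian classifier with a mixture-style covariance family.

    One Gaussian per class; the covariance family is shared by all classes
    ("equal" families additionally share the covariance values). Priors are
    the training class proportions and prediction is the plug-in Bayes rule
    in log space.
    """

    family: str = "diagonal_varying"
    params: MixtureParams | None = None
    classes: np.ndarray | None = None

    def fit(self, X, y) -> "EDDAClassifier":
        if self.family not in FAMILIES:
            raise ValueError(f"unknown covariance family {self.family!r}")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least two classes in training data")
        tau = np.zeros((X.shape[0], classes.size))
        tau[np.arange(X.shape[0]), y_idx] = 1.0
        self.params, _ = _m_step(X, tau, self.family)
        self.classes = classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        log_tau, _ = _log_resp(X, self.params)
        return np.exp(log_tau)

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def edda_fit(train_X, train_y, family: str = "diagonal_varying") -> EDDAClassifier:
    return EDDAClassifier(family=family).fit(train_X, train_y)


def edda_predict(classifier: EDDAClassifier, test_X) -> np.ndarray:
    return classifier.predict_proba(test_X)


# ---------------------------------------------------------------------------
# metrics


def brier_score(probabilities, true_labels, convention: str = "binary") -> float:
    """Mean squared difference between predicted probabilities and outcomes.

    Binary convention (two classes): mean (p_i - y_i)^2 where p_i is the
    predicted probability of the positive (second, high-use) class. The
    multiclass convention (1/(nK)) sum_ik (p_ik - y_ik)^2 keeps the range
    [0, 1] for any K. 0 is a perfect forecast; 1 is confidently wrong.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_labels)
    if P.ndim != 2 or P.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (n, K) matching labels")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("probability rows must be non-negative and sum to 1")
    classes = np.unique(y)
    if classes.size > P.shape[1]:
        raise ValueError("more observed classes than probability columns")
    Y = np.zeros_like(P)
    class_to_col = {c: j for j, c in enumerate(np.sort(classes))}
    if classes.size < P.shape[1]:
        # label values index columns directly when some classes are unseen
        class_to_col = {c: int(c) for c in classes}
    for c, j in class_to_col.items():
        Y[np.asarray(y) == c, j] = 1.0
    if convention == "binary":
        if P.shape[1] != 2:
            raise ValueError("binary convention requires exactly 2 columns")
        return float(np.mean((P[:, 1] - Y[:, 1]) ** 2))
    if convention == "multiclass":
        return float(np.mean(np.sum((P - Y) ** 2, axis=1) / P.shape[1]))
    raise ValueError("convention must be 'binary' or 'multiclass'")


@dataclass
class PredictionErrors:
    mae: float
    mape: float  # percent; NaN when undefined
    n_zero_excluded: int
    mape_defined: bool


def prediction_errors(actual, predicted) -> PredictionErrors:
    """MAE over all pairs; MAPE (percent) over pairs with nonzero actuals."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    mae = float(np.mean(np.abs(a - p)))
    nz = a != 0
    if not nz.any():
        return PredictionErrors(mae=mae, mape=float("nan"), n_zero_excluded=int(a.size), mape_defined=False)
    mape = float(100.0 * np.mean(np.abs(a[nz] - p[nz]) / np.abs(a[nz])))
    return PredictionErrors(
        mae=mae, mape=mape, n_zero_excluded=int((~nz).sum()), mape_defined=True
    )


# ---------------------------------------------------------------------------
# cross-validation report


@dataclass
class ValidationReport:
    """Per-fold and grand out-of-sample metrics plus in-sample references."""

    fold_metrics: pd.DataFrame
    grand: dict
    in_sample: dict
    split_half: dict | None = None
    seed: int | None = None
    family: str = "diagonal_varying"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "seed": self.seed,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "grand": self.grand,
            "in_sample": self.in_sample,
            "split_half": self.split_half,
        }


def _fold_metrics(
    clf: EDDAClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    data_test: pd.DataFrame | None,
    train_means: dict[str, dict] | None,
    indicator_cols: list[str] | None,
) -> dict:
    proba = clf.predict_proba(X_test)
    pred = clf.predict(X_test)
    err = float(np.mean(pred != y_test))
    convention = "binary" if proba.shape[1] == 2 else "multiclass"
    brier = brier_score(proba, y_test, convention=convention)
    # MAE/MAPE on 1..K class codes
    codes_actual = y_test.astype(float) + 1.0
    codes_pred = pred.astype(float) + 1.0
    pe = prediction_errors(codes_actual, codes_pred)
    out = {
        "classification_error": err,
        "brier": brier,
        "mae_class": pe.mae,
        "mape_class": pe.mape,
    }
    if data_test is not None and train_means is not None and indicator_cols:
        for col in indicator_cols:
            pred_vals = np.array([train_means[col][int(c)] for c in pred])
            pe_c = prediction_errors(data_test[col].values, pred_vals)
            out[f"mae_{col}"] = pe_c.mae
            out[f"mape_{col}"] = pe_c.mape
    return out


def cross_validate(
    data,
    labels,
    frames: SampleFrames,
    family: str = "diagonal_varying",
    engagement_cols: list[str] | None = None,
    feature_cols: list[str] | None = None,
) -> ValidationReport:
    """Run the frame-1 / frame-3 discriminant validation protocol.

    ``labels`` are the modal assignments of the fitted solution on frame 1.
    For each frame-3 fold an EDDA classifier is trained on the training
    part only and evaluated on the held-out part (indices never overlap);
    in-sample metrics come from training and predicting on frame 1.
    ``engagement_cols`` (e.g. face-to-face and missed-appointment counts)
    are additionally predicted by profile-conditional training means and
    scored by MAE/MAPE, the out-of-sample replication check for engagement
    measures.
    """
    df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    if feature_cols is None:
        feature_cols = list(df.columns)
    X = df[feature_cols].to_numpy(dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("labels must match the data rows")

    rows = []
    for fold_id, (tr, te) in enumerate(frames.frame3):
        if np.intersect1d(tr, te).size:
            raise AssertionError("train and test indices overlap")
        clf = edda_fit(X[tr], y[tr], family=family)
        train_means = None
        if engagement_cols:
            train_df = df.iloc[tr]
            train_means = {
                col: {
                    int(c): float(train_df.loc[y[tr] == c, col].mean())
                    for c in np.unique(y[tr])
                }
                for col in engagement_cols
            }
        m = _fold_metrics(
            clf, X[te], y[te], df.iloc[te] if engagement_cols else None,
            train_means, engagement_cols,
        )
        m["fold"] = fold_id
        m["n_train"] = int(tr.size)
        m["n_test"] = int(te.size)
        rows.append(m)
    fold_df = pd.DataFrame(rows)
    metric_cols = [c for c in fold_df.columns if c not in ("fold", "n_train", "n_test")]
    grand = {c: float(fold_df[c].mean()) for c in metric_cols}
    grand_se = {
        f"{c}_se": float(fold_df[c].std(ddof=1) / np.sqrt(len(fold_df)))
        for c in metric_cols
    }
    grand.update(grand_se)

    clf_full = edda_fit(X, y, family=family)
    in_sample = _fold_metrics(clf_full, X, y, None, None, None)
    return ValidationReport(
        fold_metrics=fold_df,
        grand=grand,
        in_sample=in_sample,
        seed=frames.seed,
        family=family,
    )


# ---------------------------------------------------------------------------
# split-half congruence


@dataclass
class SplitHalfResult:
    congruence: float
    permutation: tuple[int, ...] | None
    structural_mismatch: bool
    note: str | None = None


def _standardized_means(params: MixtureParams) -> np.ndarray:
    """Profile means in SD units of the mixture's implied grand moments."""
    w = params.weights
    mu = params.means
    grand_mean = w @ mu
    within = np.einsum("k,kj->j", w, np.stack([np.diag(c) for c in params.full_covariances()]))
    grand_var = within + w @ (mu - grand_mean) ** 2
    scale = np.sqrt(np.maximum(grand_var, np.finfo(float).tiny))
    scale[scale == 0] = 1.0
    return (mu - grand_mean) / scale


def _tucker(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.sqrt(a @ a))
    nb = float(np.sqrt(b @ b))
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def split_half_congruence(
    solution_a: ProfileSolution, solution_b: ProfileSolution
) -> SplitHalfResult:
    """Tucker congruence of profile structure between two fitted halves.

    Each solution's profile mean vectors are standardised against that
    solution's mixture-implied grand moments (mean and SD of the whole
    mixture), so each entry is a profile's location in within-sample SD
    units and indicators on large raw scales do not dominate. Profiles are
    matched across halves by the label permutation maximising the summed
    Tucker congruence; the mean matched congruence is returned. Solutions
    with different K are reported as a structural mismatch, not an
    exception.
    """
    if solution_a.params.p != solution_b.params.p:
        return SplitHalfResult(
            congruence=float("nan"), permutation=None, structural_mismatch=True,
            note="different indicator sets",
        )
    if solution_a.K != solution_b.K:
        return SplitHalfResult(
            congruence=float("nan"), permutation=None, structural_mismatch=True,
            note=f"different profile counts ({solution_a.K} vs {solution_b.K})",
        )
    Az = _standardized_means(solution_a.params)
    Bz = _standardized_means(solution_b.params)
    K = solution_a.K
    best_perm, best_val = None, -np.inf
    for perm in permutations(range(K)):
        val = np.mean([_tucker(Az[k], Bz[perm[k]]) for k in range(K)])
        if val > best_val:
            best_val, best_perm = val, perm
    return SplitHalfResult(
        congruence=float(best_val), permutation=best_perm, structural_mismatch=False
    )
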