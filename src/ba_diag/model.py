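"""Diagnostic models: 0–1 scaling, lasso selection, logistic regression.

Three classifiers share one training recipe:

- ``us_only`` — quantitative ultrasound features only;
- ``mmp7_only`` — serum MMP-7 (log-transformed) plus the age stratum;
- ``combined`` — both modalities.

Recipe: min–max scale every numeric feature to [0, 1] on the training
data (validation data reuses the training bounds and is *not* clipped);
select features with an L1-penalized logistic path, the penalty chosen by
stratified cross-validated deviance; refit the selected features with an
unpenalized maximum-likelihood logistic regression; pick the decision
threshold by the Youden index on the training ROC.

The lasso penalty is parametrized per observation (objective
``mean log-loss + lambda * ||w||_1``), so results are invariant to
duplicating the dataset at fixed lambda.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .errors import InputError, SchemaError
from .mmp7 import DEFAULT_THRESHOLDS

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingBounds:
    """Per-feature (min, max) learned on training data.

    Constant features (max == min) are dropped at fit time with a warning
    and never appear in ``bounds``.
    """

    bounds: Mapping[str, tuple[float, float]]

    @property
    def feature_names(self) -> list[str]:
        return list(self.bounds)


def fit_scaling(features: pd.DataFrame) -> ScalingBounds:
    """Learn min–max bounds; drop constant features with a warning."""
    if len(features) == 0:
        raise InputError("empty training set")
    bounds: dict[str, tuple[float, float]] = {}
    dropped = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        lo, hi = float(np.min(col)), float(np.max(col))
        if hi > lo:
            bounds[name] = (lo, hi)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped}")
    return ScalingBounds(bounds)


def apply_scaling(bounds: ScalingBounds, features: pd.DataFrame) -> pd.DataFrame:
    """Map features through the training bounds (min→0, max→1, no clipping)."""
    out = {}
    for name, (lo, hi) in bounds.bounds.items():
        if name not in features.columns:
            raise SchemaError(f"feature {name!r} missing from input")
        out[name] = (features[name].to_numpy(dtype=float) - lo) / (hi - lo)
    return pd.DataFrame(out, index=features.index)


# ---------------------------------------------------------------------------
# lasso selection
# ---------------------------------------------------------------------------

def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 30,
                        ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from the smallest all-zero lambda downward."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_points)


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # per-observation penalty: objective ∝ mean(loss) + lam * ||w||_1
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8, max_iter=5000,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def lasso_select(
    scaled: pd.DataFrame,
    y: Sequence[int],
    lambda_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Select features by cross-validated L1-penalized logistic regression.

    Returns ``(selected_feature_names, chosen_lambda)``.  Held-out
    deviance is estimated over a stratified K-fold split and the penalty
    chosen by the one-standard-error rule: the largest lambda whose mean
    deviance lies within one standard error of the minimum (the usual
    parsimony-first choice).  With a single-element ``lambda_grid`` no
    cross-validation is run.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("both classes are required for selection")
    X = scaled.to_numpy(dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    if len(lambda_grid) > 1:
        if min(np.bincount(y)) < folds:
            raise InputError(f"need at least {folds} patients per class")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        deviance = np.zeros((folds, len(lambda_grid)))
        for f, (train_idx, test_idx) in enumerate(cv.split(X, y)):
            for k, lam in enumerate(lambda_grid):
                clf = _l1_fit(X[train_idx], y[train_idx], lam)
                p = clf.predict_proba(X[test_idx])[:, 1]
                deviance[f, k] = log_loss(y[test_idx], p, labels=[0, 1])
        mean = deviance.mean(axis=0)
        se = deviance.std(axis=0, ddof=1) / np.sqrt(folds)
        k_min = int(np.argmin(mean))
        # one-standard-error rule: largest lambda whose mean deviance is
        # within one SE of the minimum (grid is sorted descending)
        k_1se = int(np.argmax(mean <= mean[k_min] + se[k_min]))
        lam = float(lambda_grid[k_1se])
    else:
        lam = float(lambda_grid[0])

    clf = _l1_fit(X, y, lam)
    coef = clf.coef_.ravel()
    selected = [name for name, c in zip(scaled.columns, coef) if c != 0.0]
    return selected, lam


# ---------------------------------------------------------------------------
# logistic refit, threshold, model container
# ---------------------------------------------------------------------------

def fit_logistic(scaled: pd.DataFrame, y: Sequence[int]) -> tuple[dict[str, float], float, bool]:
    """Unpenalized maximum-likelihood logistic fit on the selected features.

    Returns ``(coefficients, intercept, converged)``.  With zero features
    the model is intercept-only (fitted probability = training prevalence).
    Perfect separation (divergent coefficients) falls back to a lightly
    ridge-stabilized fit with a warning.
    """
    y = np.asarray(y, dtype=int)
    if scaled.shape[1] == 0:
        p = y.mean()
        p = min(max(p, 1e-12), 1 - 1e-12)
        return {}, float(np.log(p / (1 - p))), True
    if len(np.unique(y)) < 2:
        raise InputError("both classes are required for a logistic fit")

    X = scaled.to_numpy(dtype=float)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    converged = bool(clf.n_iter_[0] < clf.max_iter)
    if not converged or np.abs(clf.coef_).max() > 50.0:
        warnings.warn(
            "possible perfect separation; refitting with a small ridge penalty"
        )
        clf = LogisticRegression(C=1e3, solver="lbfgs", tol=1e-10, max_iter=5000)
        clf.fit(X, y)
        converged = bool(clf.n_iter_[0] < clf.max_iter)
    coefs = dict(zip(scaled.columns, (float(c) for c in clf.coef_.ravel())))
    return coefs, float(clf.intercept_[0]), converged


def choose_threshold(
    probabilities: Sequence[float],
    labels: Sequence[int],
    method: str = "youden",
    fixed_value: float = 0.5,
) -> float:
    """Pick a probability cutoff on the training scores.

    ``youden`` maximizes sensitivity + specificity − 1 over all cut-points
    (candidates: midpoints between adjacent distinct scores, plus the
    extremes); ties break toward higher sensitivity.  ``fixed`` returns
    ``fixed_value`` unchanged.
    """
    if method == "fixed":
        return float(fixed_value)
    if method != "youden":
        raise InputError(f"unknown threshold method {method!r}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("both classes are required to choose a threshold")

    uniq = np.unique(p)
    candidates = np.concatenate((
        [uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]],
    ))
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best = None
    for t in candidates:
        call = p > t
        sens = (call & (y == 1)).sum() / n_pos
        spec = (~call & (y == 0)).sum() / n_neg
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1]


@dataclass
class DiagnosticModel:
    """A trained diagnostic classifier with everything needed to predict.

    Coefficients live on the min–max-scaled feature space; serialization
    to/from JSON is lossless (floats stored in full repr precision).
    """

    model_kind: str  # us_only | mmp7_only | combined
    scaling: ScalingBounds
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    decision_threshold: float
    impute_medians: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def linear_score(self, features: pd.DataFrame) -> np.ndarray:
        scaled = apply_scaling(self.scaling, features)
        score = np.full(len(features), self.intercept, dtype=float)
        for name in self.selected_features:
            score += self.coefficients[name] * scaled[name].to_numpy()
        return score

    def predict_proba(self, features: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(features, Mapping):
            features = pd.DataFrame([features])
        missing = [n for n in self.scaling.feature_names if n not in features.columns]
        if missing:
            raise SchemaError(f"missing feature(s): {missing}")
        return 1.0 / (1.0 + np.exp(-self.linear_score(features)))

    def predict(self, features) -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, boolean BA calls at the stored threshold)."""
        p = self.predict_proba(features)
        return p, p > self.decision_threshold

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model_kind": self.model_kind,
            "scaling_bounds": {k: list(v) for k, v in self.scaling.bounds.items()},
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "decision_threshold": self.decision_threshold,
            "impute_medians": self.impute_medians,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiagnosticModel":
        return cls(
            model_kind=d["model_kind"],
            scaling=ScalingBounds({k: tuple(v) for k, v in d["scaling_bounds"].items()}),
            selected_features=list(d["selected_features"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            decision_threshold=float(d["decision_threshold"]),
            impute_medians=dict(d.get("impute_medians", {})),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiagnosticModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# training entry points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Training hyper-parameters (all recorded in the model metadata)."""

    lambda_grid: Sequence[float] | None = None
    folds: int = 5
    seed: int = 0
    threshold_method: str = "youden"
    fixed_threshold: float = 0.5


def train_model(
    features: pd.DataFrame,
    y: Sequence[int],
    model_kind: str = "us_only",
    cfg: ModelConfig | None = None,
    impute_medians: Mapping[str, float] | None = None,
) -> DiagnosticModel:
    """Scale → lasso-select → unpenalized refit → Youden threshold."""
    cfg = cfg or ModelConfig()
    y = np.asarray(y, dtype=int)
    bounds = fit_scaling(features)
    scaled = apply_scaling(bounds, features)
    selected, lam = lasso_select(scaled, y, cfg.lambda_grid, cfg.folds, cfg.seed)
    coefs, intercept, converged = fit_logistic(scaled[selected], y)
    model = DiagnosticModel(
        model_kind=model_kind,
        scaling=bounds,
        selected_features=selected,
        coefficients=coefs,
        intercept=intercept,
        decision_threshold=0.5,
        impute_medians=dict(impute_medians or {}),
        metadata={
            "lambda": lam, "folds": cfg.folds, "seed": cfg.seed,
            "converged": converged, "n_train": int(len(y)),
            "prevalence_train": float(y.mean()),
            "threshold_method": cfg.threshold_method,
        },
    )
    probs = model.predict_proba(features)
    model.decision_threshold = choose_threshold(
        probs, y, cfg.threshold_method, cfg.fixed_threshold
    )
    return model


def mmp7_design(mmp7: Sequence[float], age_days: Sequence[int],
                index=None) -> pd.DataFrame:
    """MMP-7 model inputs: log10(1 + concentration) and the age stratum.

    The age-stratum indicator is 1 for infants ≤ 30 days old, where the
    clinical positivity threshold is higher.
    """
    mmp7 = np.asarray(mmp7, dtype=float)
    age = np.asarray(age_days, dtype=float)
    return pd.DataFrame(
        {
            "mmp7_log10": np.log10(1.0 + mmp7),
            "age_le_30": (age <= DEFAULT_THRESHOLDS.age_cut).astype(float),
        },
        index=index,
    )


def build_combined(
    us_features: pd.DataFrame,
    mmp7: Sequence[float],
    age_days: Sequence[int],
    y: Sequence[int],
    cfg: ModelConfig | None = None,
    impute_medians: Mapping[str, float] | None = None,
) -> tuple[DiagnosticModel, list]:
    """Train the combined ultrasound + MMP-7 model.

    Patients with missing MMP-7 are excluded from combined training and
    returned in the exclusion list (never dropped silently).
    """
    mmp7 = np.asarray(mmp7, dtype=float)
    y = np.asarray(y, dtype=int)
    ok = np.isfinite(mmp7)
    excluded = list(np.asarray(us_features.index)[~ok])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} patient(s) without MMP-7")
    us = us_features.loc[ok]
    design = pd.concat(
        [us, mmp7_design(mmp7[ok], np.asarray(age_days)[ok], index=us.index)],
        axis=1,
    )
    model = train_model(design, y[ok], "combined", cfg, impute_medians)
    return model, excluded
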