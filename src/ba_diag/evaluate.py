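"""Diagnostic-accuracy statistics.

- :func:`roc_and_auc` — tie-corrected AUC (the probability a random case
  scores above a random control, ties counting one half) with a 95% CI
  from DeLong's structural-components variance;
- :func:`delong_compare` — paired DeLong test between two scores on the
  same patients;
- :func:`confusion_metrics` — sensitivity/specificity/accuracy with exact
  Clopper–Pearson 95% intervals, formatted to one decimal place with
  round-half-away-from-zero, matching clinical reporting style;
- :func:`calibration` — reliability curve over equal-frequency bins;
- :func:`subgroup_report` — the same metrics within subgroups at the same
  trained threshold;
- :func:`cohort_comparison` — descriptive Table-1-style comparison
  (chi-squared for categorical, Wilcoxon rank-sum for continuous columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise InputError("both classes must be present")
    if not set(classes) <= {0, 1}:
        raise InputError("labels must be coded 0/1")


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank_psi(cases: np.ndarray, controls: np.ndarray):
    """Structural components V10 (per case) and V01 (per control).

    psi(X, Y) = 1 if X > Y, 0.5 if X == Y, 0 otherwise; V10_i is the mean
    of psi over controls, V01_j the mean over cases.  AUC is the mean of
    either vector.
    """
    m, n = len(cases), len(controls)
    # pairwise comparison is fine at clinical cohort sizes
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), psi


def auc_statistic(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected rank AUC: (concordant + ½ ties) / all cross pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    v10, _, _ = _midrank_psi(scores[labels == 1], scores[labels == 0])
    return float(v10.mean())


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """(AUC, DeLong variance) for one score vector."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    v10, v01, _ = _midrank_psi(scores[labels == 1], scores[labels == 0])
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_and_auc(
    scores: Sequence[float], labels: Sequence[int], ci_level: float = 0.95
) -> dict:
    """ROC points plus AUC with a DeLong normal-approximation CI.

    The CI is truncated to [0, 1].  Returns a dict with ``fpr``, ``tpr``,
    ``thresholds``, ``auc``, ``auc_ci`` and ``auc_se``.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    auc, var = delong_variance(scores, labels)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return {
        "fpr": fpr, "tpr": tpr, "thresholds": thr,
        "auc": auc, "auc_se": se, "auc_ci": (float(lo), float(hi)),
    }


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> dict:
    """Paired DeLong test for the difference of two correlated AUCs.

    Identical score vectors give difference 0 and p = 1 by convention
    (the variance of the difference is zero there).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(a) != len(b) or len(a) != len(labels):
        raise InputError("paired scores must have equal length")
    _check_binary(labels)

    cases, controls = labels == 1, labels == 0
    v10a, v01a, _ = _midrank_psi(a[cases], a[controls])
    v10b, v01b, _ = _midrank_psi(b[cases], b[controls])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
        z = 0.0 if np.isclose(diff, 0.0) else np.inf
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": diff,
            "z": float(z), "p_value": float(p)}


# ---------------------------------------------------------------------------
# confusion metrics with exact CIs
# ---------------------------------------------------------------------------

def format_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP))


def _proportion_with_ci(k: int, n: int, ci_level: float) -> dict:
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="beta")
    est = k / n
    return {
        "estimate": est, "ci": (float(lo), float(hi)),
        "percent": format_percent(est),
        "percent_ci": (format_percent(float(lo)), format_percent(float(hi))),
        "numerator": int(k), "denominator": int(n),
    }


@dataclass(frozen=True)
class AccuracyReport:
    """Sensitivity/specificity/accuracy with exact binomial 95% CIs."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: dict
    specificity: dict
    accuracy: dict
    threshold: float | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "threshold": self.threshold,
        }
        if self.auc is not None:
            d["auc"] = self.auc
            d["auc_ci"] = list(self.auc_ci)
        return d


def confusion_metrics(
    calls: Sequence[bool],
    labels: Sequence[int],
    ci_level: float = 0.95,
    threshold: float | None = None,
) -> AccuracyReport:
    """Confusion counts and exact-interval diagnostic metrics.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    (TP+TN)/total; each with a Clopper–Pearson CI.  Percentages are
    reported to one decimal, round-half-away-from-zero.
    """
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if len(calls) == 0 or len(calls) != len(labels):
        raise InputError("calls and labels must be non-empty and aligned")
    tp = int((calls & (labels == 1)).sum())
    fn = int((~calls & (labels == 1)).sum())
    tn = int((~calls & (labels == 0)).sum())
    fp = int((calls & (labels == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise InputError("both classes must be present")
    return AccuracyReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=_proportion_with_ci(tp, tp + fn, ci_level),
        specificity=_proportion_with_ci(tn, tn + fp, ci_level),
        accuracy=_proportion_with_ci(tp + tn, len(labels), ci_level),
        threshold=threshold,
    )


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    ci_level: float = 0.95,
) -> AccuracyReport:
    """Full report: AUC with DeLong CI plus threshold-based metrics."""
    roc = roc_and_auc(scores, labels, ci_level)
    calls = np.asarray(scores, dtype=float) > threshold
    rep = confusion_metrics(calls, labels, ci_level, threshold=threshold)
    return AccuracyReport(
        tp=rep.tp, fn=rep.fn, tn=rep.tn, fp=rep.fp,
        sensitivity=rep.sensitivity, specificity=rep.specificity,
        accuracy=rep.accuracy, threshold=threshold,
        auc=roc["auc"], auc_ci=roc["auc_ci"],
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration(
    probabilities: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Reliability curve over equal-frequency probability bins.

    Returns one row per occupied bin: mean predicted probability,
    observed event fraction, and count.  Duplicate bin edges (heavily
    tied predictions) are merged.
    """
    if n_bins < 2:
        raise InputError("n_bins must be at least 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.min() < 0 or p.max() > 1:
        raise InputError("probabilities must lie in [0, 1]")
    if len(np.unique(p)) == 1:
        bins = pd.Series(0, index=range(len(p)))
    else:
        bins = pd.qcut(p, q=n_bins, labels=False, duplicates="drop")
    df = pd.DataFrame({"bin": bins, "pred": p, "obs": y})
    out = df.groupby("bin").agg(
        mean_predicted=("pred", "mean"),
        observed_fraction=("obs", "mean"),
        count=("obs", "size"),
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# subgroups and cohort comparison
# ---------------------------------------------------------------------------

def subgroup_report(
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Sequence,
    threshold: float,
    ci_level: float = 0.95,
) -> dict[str, AccuracyReport]:
    """Per-group reports with the SAME model scores and threshold.

    Groups containing a single class get confusion metrics without an
    AUC (with a warning); empty groups are omitted with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    reports: dict[str, AccuracyReport] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:  # pragma: no cover - unreachable via unique()
            warnings.warn(f"subgroup {g!r} is empty; omitted")
            continue
        ls, ss = labels[sel], scores[sel]
        if len(np.unique(ls)) < 2:
            warnings.warn(f"subgroup {g!r} has one class; AUC omitted")
            calls = ss > threshold
            tp = int((calls & (ls == 1)).sum()); fn = int((~calls & (ls == 1)).sum())
            tn = int((~calls & (ls == 0)).sum()); fp = int((calls & (ls == 0)).sum())
            reports[str(g)] = AccuracyReport(
                tp=tp, fn=fn, tn=tn, fp=fp,
                sensitivity=_proportion_with_ci(tp, tp + fn, ci_level) if tp + fn else None,
                specificity=_proportion_with_ci(tn, tn + fp, ci_level) if tn + fp else None,
                accuracy=_proportion_with_ci(tp + tn, int(sel.sum()), ci_level),
                threshold=threshold,
            )
        else:
            reports[str(g)] = evaluate_scores(ss, ls, threshold, ci_level)
    return reports


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    return series.nunique(dropna=True) <= 2


def cohort_comparison(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Descriptive between-cohort comparison with unadjusted p-values.

    Categorical columns (object dtype or ≤2 distinct values) are compared
    with Pearson's chi-squared test (no continuity correction) and shown
    as n (%); continuous columns with the Wilcoxon rank-sum test and
    shown as median (Q1, Q3).  Empty columns are skipped with a note.
    """
    if columns is None:
        columns = [c for c in table_a.columns if c in table_b.columns]
    rows = []
    for col in columns:
        a, b = table_a[col].dropna(), table_b[col].dropna()
        if len(a) == 0 or len(b) == 0:
            rows.append({"variable": col, "cohort_a": "", "cohort_b": "",
                         "p_value": np.nan, "test": "skipped (empty column)"})
            continue
        if _is_categorical(a):
            counts = pd.crosstab(
                np.r_[np.zeros(len(a)), np.ones(len(b))],
                pd.concat([a, b]).to_numpy(),
            )
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
            top = counts.columns[-1]
            ka, kb = (a == top).sum(), (b == top).sum()
            rows.append({
                "variable": f"{col} ({top})",
                "cohort_a": f"{ka} ({format_percent(ka / len(a))})",
                "cohort_b": f"{kb} ({format_percent(kb / len(b))})",
                "p_value": float(p), "test": "chi-squared",
            })
        else:
            stat = stats.mannwhitneyu(a, b, alternative="two-sided")
            qa = np.percentile(a, [50, 25, 75])
            qb = np.percentile(b, [50, 25, 75])
            rows.append({
                "variable": col,
                "cohort_a": f"{qa[0]:.1f} ({qa[1]:.1f}, {qa[2]:.1f})",
                "cohort_b": f"{qb[0]:.1f} ({qb[1]:.1f}, {qb[2]:.1f})",
                "p_value": float(stat.pvalue), "test": "wilcoxon-rank-sum",
            })
    return pd.DataFrame(rows)
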