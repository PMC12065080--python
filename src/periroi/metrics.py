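"""Statistical evaluation layer: ROC/AUC with DeLong inference, paired
DeLong AUC comparison, operating-point metrics, decision-curve analysis and
calibration curves.

The AUC is the tie-corrected pairwise statistic: the mean over all
(positive, negative) pairs of 1 if the positive scores higher, 1/2 on a
tie, 0 otherwise (equivalently the Mann-Whitney U statistic scaled to
[0, 1]). DeLong variance and covariance come from the structural-component
(placement-value) estimator computed with midranks, which handles ties and
runs in O(n log n).

Net benefit at threshold probability t is TP/n - FP/n * t/(1-t), with a
case treated iff its score is >= t; "treat all" treats every case and
"treat none" is identically zero. Calibration uses equal-width bins on
[0, 1]; empty bins are reported with count 0 and NaN observed frequency,
never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "NetBenefitCurve",
    "CalibrationCurve",
    "auc",
    "delong_ci",
    "delong_test",
    "operating_point",
    "youden_threshold",
    "decision_curve",
    "calibration_curve",
    "evaluate_scores",
    "report_grid",
]

#: canonical column ordering for grid reports
MODE_ORDER = ("2.5D1", "2.5D2", "2.5D3", "2D", "3D")


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n_pos: int
    n_neg: int


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray  # identically zero, kept for plotting symmetry


@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray  # NaN for empty bins
    observed_frequency: np.ndarray  # NaN for empty bins
    counts: np.ndarray


def _validate(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return s, y.astype(int)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores, labels):
    """AUC and the DeLong placement values V10 (per positive), V01 (per negative)."""
    s, y = _validate(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    # placement of each positive among the negatives, and vice versa
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    a = v10.mean()
    return a, v10, v01


def auc(scores, labels) -> float:
    """Tie-corrected pairwise AUC (Mann-Whitney statistic)."""
    a, _, _ = _structural_components(scores, labels)
    return float(a)


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval for the AUC, clipped to [0, 1].

    With zero estimated variance and a degenerate AUC of exactly 0 or 1 the
    point interval is returned with a warning.
    """
    a, v10, v01 = _structural_components(scores, labels)
    if len(v10) < 2 or len(v01) < 2:
        raise ValueError("need at least 2 cases per class for a DeLong CI")
    var = _delong_var(v10, v01)
    if var <= 0:
        if a in (0.0, 1.0):
            warnings.warn(
                "degenerate zero DeLong variance with AUC in {0,1}; "
                "returning a point interval",
                UserWarning,
            )
        return (float(a), float(a))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def delong_test(scores_a, scores_b, labels) -> dict[str, float]:
    """Paired DeLong comparison of two correlated AUCs on identical cases.

    Returns ``{"z": ..., "p": ..., "auc_a": ..., "auc_b": ...}`` with a
    two-sided normal p-value. Identical score vectors give z = 0, p = 1.
    """
    sa = np.asarray(scores_a, dtype=np.float64)
    sb = np.asarray(scores_b, dtype=np.float64)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    aa, v10a, v01a = _structural_components(sa, labels)
    ab, v10b, v01b = _structural_components(sb, labels)
    m, n = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (d10.var(ddof=1) / m if m > 1 else 0.0) + (
        d01.var(ddof=1) / n if n > 1 else 0.0
    )
    diff = aa - ab
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if var <= 0 and diff == 0 else float(2.0 * stats.norm.sf(abs(z)))
    return {"z": float(z), "p": p, "auc_a": float(aa), "auc_b": float(ab)}


def _confusion(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties -> lowest)."""
    s, y = _validate(scores, labels)
    candidates = np.unique(s)
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:  # ascending, so strict improvement keeps the lowest tie
        tp, fp, fn, tn = _confusion(s, y, t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def operating_point(scores, labels, threshold: Optional[float] = None) -> RocResult:
    """AUC + CI and sensitivity/specificity/accuracy at a threshold.

    Without an explicit threshold the Youden-optimal one is chosen on these
    same scores; to avoid leakage across cohorts, choose the threshold on
    the training scores and pass it in for validation cohorts.
    """
    s, y = _validate(scores, labels)
    if threshold is None:
        threshold = youden_threshold(s, y)
    tp, fp, fn, tn = _confusion(s, y, threshold)
    a = auc(s, y)
    # DeLong needs >= 2 cases per class; degrade to a point interval below that
    ci = delong_ci(s, y) if min(y.sum(), len(y) - y.sum()) >= 2 else (a, a)
    return RocResult(
        auc=a,
        ci95=ci,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        threshold=float(threshold),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def decision_curve(
    scores, labels, thresholds: Optional[Sequence[float]] = None
) -> NetBenefitCurve:
    """Net benefit of the model, of treat-all and of treat-none.

    Default threshold grid 0.01..0.99 step 0.01; t = 1 is excluded (the
    t/(1-t) weight diverges).
    """
    s, y = _validate(scores, labels)
    t = (
        np.arange(0.01, 1.0, 0.01)
        if thresholds is None
        else np.asarray(thresholds, dtype=np.float64)
    )
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    model = np.empty_like(t)
    for i, ti in enumerate(t):
        tp, fp, _, _ = _confusion(s, y, ti)
        model[i] = tp / n - fp / n * ti / (1 - ti)
    treat_all = prev - (1 - prev) * t / (1 - t)
    return NetBenefitCurve(
        thresholds=t, model=model, treat_all=treat_all, treat_none=np.zeros_like(t)
    )


def calibration_curve(scores, labels, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width reliability curve on [0, 1]."""
    s, y = _validate(scores, labels)
    if len(s) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} cases")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("calibration requires probability scores in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if counts[b]:
            mean_pred[b] = s[idx == b].mean()
            obs[b] = y[idx == b].mean()
    return CalibrationCurve(
        bin_edges=edges, mean_predicted=mean_pred, observed_frequency=obs, counts=counts
    )


# -- grid reporting ---------------------------------------------------------

def evaluate_scores(
    score_sets: Mapping[str, "ScoreSetLike"],
    threshold_cohort: str = "train",
) -> dict[str, RocResult]:
    """Per-cohort RocResults with the operating threshold chosen on the
    training cohort and frozen for validation cohorts."""
    if threshold_cohort in score_sets:
        s, y = score_sets[threshold_cohort].arrays()
        thr = youden_threshold(s, y)
    else:
        thr = None
    out = {}
    for cohort, ss in score_sets.items():
        s, y = ss.arrays()
        out[cohort] = operating_point(s, y, threshold=thr)
    return out


def report_grid(
    results: Mapping[tuple, Mapping[str, "ScoreSetLike"]],
    reference_cell: Optional[tuple] = None,
) -> pd.DataFrame:
    """Tabular diagnostic-performance report for a configuration grid.

    One row per (mode, radius, scenario, cohort) with AUC, 95% CI,
    sensitivity, specificity, accuracy and threshold; if a reference cell is
    given, paired DeLong z/p against it per cohort. Rows are ordered
    2.5D1, 2.5D2, 2.5D3, 2D, 3D, then by radius and scenario.
    """
    rows = []
    for cell, per_cohort in results.items():
        mode, radius, scenario = cell
        evals = evaluate_scores(per_cohort)
        for cohort, rr in evals.items():
            row = {
                "mode": mode,
                "radius_mm": radius,
                "scenario": scenario,
                "cohort": cohort,
                "auc": rr.auc,
                "ci_lo": rr.ci95[0],
                "ci_hi": rr.ci95[1],
                "sens": rr.sensitivity,
                "spec": rr.specificity,
                "acc": rr.accuracy,
                "threshold": rr.threshold,
            }
            if reference_cell is not None:
                if reference_cell not in results:
                    raise ValueError(f"reference cell {reference_cell} missing from results")
                ref = results[reference_cell].get(cohort)
                if ref is None:
                    raise ValueError(
                        f"reference cell lacks cohort {cohort!r} scores"
                    )
                sa, ya = per_cohort[cohort].arrays()
                sb, yb = ref.arrays()
                if not np.array_equal(ya, yb):
                    raise ValueError("reference scores are not paired with cell scores")
                res = delong_test(sa, sb, ya)
                row["delong_z_vs_ref"] = res["z"]
                row["delong_p_vs_ref"] = res["p"]
            rows.append(row)
    df = pd.DataFrame(rows)
    mode_rank = {m: i for i, m in enumerate(MODE_ORDER)}
    cohort_rank = {"train": 0, "val1": 1, "val2": 2}
    df = df.sort_values(
        by=["mode", "radius_mm", "scenario", "cohort"],
        key=lambda col: (
            col.map(mode_rank)
            if col.name == "mode"
            else col.map(cohort_rank) if col.name == "cohort" else col
        ),
    ).reset_index(drop=True)
    return df
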