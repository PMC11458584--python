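"""Confusion-matrix metrics, run-level search statistics and one-way ANOVA.

The metric suite follows a common clinical-ML reporting convention:
accuracy, sensitivity (TPR), specificity (TNR), precision,
F-score, and an "AUC" defined as (sensitivity + specificity) / 2 — i.e. the
balanced accuracy.  A score-based ranking ROC-AUC is available separately
(:func:`ranking_auc`) because the two differ whenever a classifier's scores
carry more information than its hard labels.

Zero-denominator metrics are defined as 0 with a warning, so downstream
summary tables stay total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RunSummary",
    "AnovaTable",
    "confusion_counts",
    "metric_set",
    "ranking_auc",
    "run_summary",
    "anova_one_way",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts; positive class is label 1."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one prediction is required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """The full evaluation row: all rates in [0, 1].

    ``fitted_time`` (seconds) is carried for reporting but is
    hardware-dependent and never asserted.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auc: float
    fitted_time: float | None = None


@dataclass
class RunSummary:
    """Cross-run statistics of one optimizer's best-per-run fitnesses."""

    average_error: float
    average_select_size: float
    mean_fitness: float
    best_fitness: float
    std_fitness: float
    reference_optimum: float
    n_runs: int


@dataclass
class AnovaTable:
    """Classical one-way ANOVA decomposition.

    ``residual_zero`` flags the degenerate all-groups-identical case where
    MS_residual = 0 and F is unbounded.
    """

    ss_treatment: float
    df_treatment: int
    ms_treatment: float
    ss_residual: float
    df_residual: int
    ms_residual: float
    f_statistic: float
    p_value: float
    residual_zero: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_treatment + self.ss_residual

    @property
    def df_total(self) -> int:
        return self.df_treatment + self.df_residual

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular layout: Treatment / Residual / Total rows."""
        f_label = f"F ({self.df_treatment}, {self.df_residual}) = {self.f_statistic:.4g}"
        return pd.DataFrame(
            {
                "SS": [self.ss_treatment, self.ss_residual, self.ss_total],
                "DF": [self.df_treatment, self.df_residual, self.df_total],
                "MS": [self.ms_treatment, self.ms_residual, float("nan")],
                "F (DFn, DFd)": [f_label, "", ""],
                "P value": [f"{self.p_value:.4g}", "", ""],
            },
            index=["Treatment (between columns)", "Residual (within columns)", "Total"],
        )


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty vectors")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = sorted(set(np.unique(arr)) - {0, 1})
        if bad:
            raise ValueError(f"{name} contains non-binary values {bad}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has a zero denominator; defined as 0", stacklevel=3)
        return 0.0
    return num / den


def metric_set(c: ConfusionCounts, fitted_time: float | None = None) -> MetricSet:
    """Compute the full metric row from confusion counts.

    AUC here is the balanced-accuracy form (sensitivity + specificity) / 2
    computed from hard predictions; see :func:`ranking_auc` for the
    score-based ROC variant.
    """
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if precision + sensitivity == 0:
        f_score = 0.0
    else:
        f_score = 2.0 * sensitivity * precision / (sensitivity + precision)
    auc = 0.5 * (sensitivity + specificity)
    return MetricSet(accuracy, sensitivity, specificity, precision, f_score, auc, fitted_time)


def ranking_auc(y_true, scores) -> float:
    """Score-based ROC-AUC (probability a positive outranks a negative)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


def run_summary(traces, reference_optimum: float | None = None) -> RunSummary:
    """Summarize a list of search traces from independent runs.

    Per-run error e_i = f(x_i) - f(x_optimal) uses the supplied reference
    optimum, or — in auto mode — the best fitness observed across all the
    traces, which makes every e_i >= 0.  ``std_fitness`` uses the sample
    (n-1) convention; a single run reports 0.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace is required")
    bests = np.array([t.best.fitness for t in traces], dtype=float)
    ref = float(bests.min()) if reference_optimum is None else float(reference_optimum)
    ratios = [t.best.select_ratio for t in traces if t.best.mask]
    ratios = ratios or [np.nan]  # tuner traces carry no masks
    return RunSummary(
        average_error=float(np.mean(bests - ref)),
        average_select_size=float(np.mean(ratios)),
        mean_fitness=float(np.mean(bests)),
        best_fitness=float(bests.min()),
        std_fitness=float(np.std(bests, ddof=1)) if len(bests) > 1 else 0.0,
        reference_optimum=ref,
        n_runs=len(bests),
    )


def anova_one_way(groups) -> AnovaTable:
    """One-way ANOVA across treatment groups.

    ``groups`` is a 2-D array (observations x treatments) or a list of
    per-treatment observation vectors (equal or unequal lengths).  The p
    value comes from the F distribution with (DF_treatment, DF_residual)
    degrees of freedom.
    """
    if isinstance(groups, np.ndarray) and groups.ndim == 2:
        cols = [groups[:, j].astype(float) for j in range(groups.shape[1])]
    else:
        cols = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(cols) < 2:
        raise ValueError("at least 2 treatment groups are required")
    if any(len(g) < 2 for g in cols):
        raise ValueError("every group needs at least 2 observations")

    all_obs = np.concatenate(cols)
    grand = all_obs.mean()
    ss_treat = float(sum(len(g) * (g.mean() - grand) ** 2 for g in cols))
    ss_resid = float(sum(((g - g.mean()) ** 2).sum() for g in cols))
    df_treat = len(cols) - 1
    df_resid = int(sum(len(g) for g in cols)) - len(cols)
    ms_treat = ss_treat / df_treat
    ms_resid = ss_resid / df_resid
    if ms_resid == 0.0:
        return AnovaTable(
            ss_treat, df_treat, ms_treat, ss_resid, df_resid, ms_resid,
            f_statistic=float("inf") if ms_treat > 0 else float("nan"),
            p_value=0.0 if ms_treat > 0 else float("nan"),
            residual_zero=True,
        )
    f_stat = ms_treat / ms_resid
    p = float(stats.f.sf(f_stat, df_treat, df_resid))
    return AnovaTable(ss_treat, df_treat, ms_treat, ss_resid, df_resid, ms_resid, f_stat, p)
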