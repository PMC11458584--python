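"""Minimal plotting helpers: convergence overlay and ROC curve.

Matplotlib is imported lazily so the rest of the package works headless
without it installed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_convergence", "plot_roc"]


def plot_convergence(traces: dict, ax=None):
    """Overlay best-so-far curves, one line per optimizer (mean over runs)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, runs in traces.items():
        longest = max(len(t.best_so_far) for t in runs)
        curves = np.full((len(runs), longest), np.nan)
        for i, t in enumerate(runs):
            c = np.asarray(t.best_so_far)
            curves[i, : len(c)] = c
            curves[i, len(c):] = c[-1]  # hold the final best
        ax.plot(np.arange(1, longest + 1), np.nanmean(curves, axis=0), label=name)
    ax.set_xlabel("fitness evaluations")
    ax.set_ylabel("best-so-far fitness")
    ax.legend()
    return ax


def plot_roc(y_true, scores, ax=None):
    """Plot the ROC curve of predicted scores."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if ax is None:
        _, ax = plt.subplots()
    fpr, tpr, _ = roc_curve(np.asarray(y_true), np.asarray(scores))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    return ax
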