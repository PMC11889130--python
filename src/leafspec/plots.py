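"""Basic diagnostic figures (matplotlib is imported lazily).

Two plots cover the usual visual checks on a fitted pipeline: a
predicted-vs-measured scatter for one model, and side-by-side box plots
of the SPAD predictions of several models against the measured values.
"""

from __future__ import annotations

import numpy as np


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(4.5, 4.5))
    return ax


def predicted_vs_measured(measured, predicted, label: str | None = None, ax=None):
    """1:1 scatter of predicted against measured SPAD."""
    ax = _get_axes(ax)
    y = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    lo = min(y.min(), p.min())
    hi = max(y.max(), p.max())
    pad = 0.05 * (hi - lo or 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], "k--", lw=1, label="1:1")
    ax.scatter(y, p, s=18, alpha=0.8, label=label)
    ax.set_xlabel("measured SPAD")
    ax.set_ylabel("predicted SPAD")
    if label:
        ax.legend(frameon=False)
    return ax


def prediction_boxplot(measured, predictions: dict[str, np.ndarray], ax=None):
    """Box plots of measured SPAD next to each model's predictions."""
    ax = _get_axes(ax)
    labels = ["measured"] + list(predictions)
    data = [np.asarray(measured, dtype=float)] + [
        np.asarray(v, dtype=float) for v in predictions.values()
    ]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("SPAD")
    return ax
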