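"""Optional matplotlib views of results (PR curves, novelty histograms)."""

from __future__ import annotations

import numpy as np


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install senoscreen[plot])") from exc
    return plt


def plot_pr_curve(pr_result, label: str = "", ax=None):
    """Plot a precision–recall curve with its bootstrap auPRC CI in the label."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    lo, hi = pr_result.ci
    ax.step(
        pr_result.recall,
        pr_result.precision,
        where="post",
        label=f"{label} auPRC={pr_result.auprc:.3f} [{lo:.3f}, {hi:.3f}]",
    )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left")
    return ax


def plot_novelty_histogram(hist_table, ax=None):
    """Bar plot of consensus-hit match-degree distribution on [0, 1]."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    widths = hist_table["bin_right"] - hist_table["bin_left"]
    ax.bar(
        hist_table["bin_left"],
        hist_table["count"],
        width=widths,
        align="edge",
        edgecolor="black",
    )
    ax.set_xlabel("max Tanimoto to training actives")
    ax.set_ylabel("consensus hits")
    return ax
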