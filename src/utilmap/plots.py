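"""Diagnostic figures: observed-vs-predicted scatter, error histogram and
empirical CDF overlay for one or more fitted mapping models."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["scatter_observed_predicted", "error_histogram", "cdf_overlay"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def scatter_observed_predicted(observed, predictions: dict[str, np.ndarray], path) -> Path:
    plt = _axes()
    n = len(predictions)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    observed = np.asarray(observed, dtype=float)
    for ax, (label, pred) in zip(axes.ravel(), predictions.items()):
        ax.scatter(observed, pred, s=6, alpha=0.4)
        lims = [min(observed.min(), np.min(pred)), 1.05]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(label)
        ax.set_xlabel("observed utility")
        ax.set_ylabel("predicted")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def error_histogram(observed, predictions: dict[str, np.ndarray], path) -> Path:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    observed = np.asarray(observed, dtype=float)
    for label, pred in predictions.items():
        ax.hist(np.asarray(pred) - observed, bins=40, histtype="step", label=label)
    ax.set_xlabel("prediction error")
    ax.set_ylabel("count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def cdf_overlay(observed, predictions: dict[str, np.ndarray], path) -> Path:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    observed = np.asarray(observed, dtype=float)
    grid = np.sort(observed)
    ax.step(grid, np.linspace(0, 1, len(grid)), where="post", color="k", label="Observed")
    for label, pred in predictions.items():
        s = np.sort(np.asarray(pred, dtype=float))
        ax.step(s, np.linspace(0, 1, len(s)), where="post", lw=0.9, label=label)
    ax.set_xlabel("utility")
    ax.set_ylabel("empirical CDF")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
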