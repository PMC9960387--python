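"""Figure helpers: importance rankings, RFE curves, confusion matrices,
saliency overlays and slope-score bars. All functions write a PNG and return
the matplotlib figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_importance", "plot_rfe_curve", "plot_confusion",
           "plot_saliency_overlay", "plot_slope_importance"]


def plot_importance(importance: pd.Series, path, top: int = 10):
    """Horizontal bars for the top features, min-max rescaled for display."""
    imp = importance.sort_values(ascending=False).head(top)
    rng = imp.max() - imp.min()
    display = (imp - imp.min()) / rng if rng > 0 else imp
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(imp) + 1))
    ax.barh(imp.index[::-1], display[::-1], color="tab:blue")
    ax.set_xlabel("impurity importance (min-max rescaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_rfe_curve(curve: pd.DataFrame, path):
    """Accuracy vs retained feature count (columns n_features, accuracy)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["n_features"], curve["accuracy"], marker=".", lw=1)
    best = curve.loc[curve["accuracy"].idxmax()]
    ax.axvline(best["n_features"], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("number of retained features")
    ax.set_ylabel("LOSO accuracy")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_confusion(counts: np.ndarray, classes, path):
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > counts.max() / 2 else "black")
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_saliency_overlay(values: np.ndarray, saliency: np.ndarray, path,
                          title: str = ""):
    """Trace coloured by per-timestep saliency (heat-map overlay)."""
    fig, ax = plt.subplots(figsize=(7, 3))
    t = np.arange(values.size)
    sc = ax.scatter(t, values, c=saliency, cmap="inferno", s=4)
    ax.set_xlabel("sample")
    ax.set_ylabel("normalised conductance")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="saliency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_slope_importance(scores: dict, path):
    """Grouped bars of w+/w- normalised scores per class.

    ``scores`` maps class name -> dict with w_plus_norm / w_minus_norm.
    """
    names = list(scores)
    wp = [scores[n]["w_plus_norm"] or 0.0 for n in names]
    wm = [scores[n]["w_minus_norm"] or 0.0 for n in names]
    x = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(x - 0.18, wp, width=0.36, label="rising (w+)")
    ax.bar(x + 0.18, wm, width=0.36, label="falling (w-)")
    ax.set_xticks(x, names)
    ax.set_ylabel("normalised slope importance")
    ax.axhline(0.5, ls=":", c="gray", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
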