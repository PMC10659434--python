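"""Basic figures for the report bundle: volcano, notched box plots,
clustered ΔTE heatmap, and the pause-score scatter.  Plain matplotlib,
deterministic given the data; aesthetics are intentionally minimal."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["volcano", "notched_box", "delta_heatmap", "pause_scatter"]


def volcano(table: pd.DataFrame, fdr: float, path, title: str = "") -> None:
    """log2 fold change vs -log10 FDR, significant genes highlighted."""
    q = table["qvalue"].to_numpy()
    x = table["log2fc"].to_numpy()
    with np.errstate(divide="ignore"):
        y = -np.log10(np.maximum(q, 1e-300))
    sig = q < fdr
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x[~sig], y[~sig], s=4, c="grey", alpha=0.5, linewidths=0)
    ax.scatter(x[sig], y[sig], s=6, c="crimson", linewidths=0)
    ax.axhline(-np.log10(fdr), ls=":", c="k", lw=0.8)
    ax.set_xlabel("log2 ΔTE")
    ax.set_ylabel("-log10 FDR")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def notched_box(groups: dict[str, np.ndarray], path, ylabel: str = "log2 ΔTE") -> None:
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    data = [d[np.isfinite(d)] for d in data]
    fig, ax = plt.subplots(figsize=(1.2 * max(len(labels), 3) + 1, 4))
    ax.boxplot(data, notch=True, tick_labels=labels, showfliers=False)
    ax.axhline(0.0, ls=":", c="k", lw=0.8)
    ax.set_ylabel(ylabel)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def delta_heatmap(delta: pd.DataFrame, order: list[str], path) -> None:
    sub = delta.loc[[g for g in order if g in delta.index]]
    fig, ax = plt.subplots(figsize=(4, max(3, 0.12 * len(sub))))
    im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="RdBu",
                   vmin=-4, vmax=4)
    ax.set_xticks(range(sub.shape[1]))
    ax.set_xticklabels(sub.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 ΔTE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pause_scatter(pairs: pd.DataFrame, highlight_mask, path,
                  labels: tuple[str, str] = ("condition A", "condition B")) -> None:
    m = np.asarray(highlight_mask, dtype=bool)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pairs["score_a"][~m], pairs["score_b"][~m], s=5, c="grey",
               alpha=0.5, linewidths=0)
    ax.scatter(pairs["score_a"][m], pairs["score_b"][m], s=8, c="red",
               linewidths=0)
    lim = max(float(pairs.max().max()) * 1.05, 1.0)
    ax.plot([0, lim], [0, lim], ls=":", c="k", lw=0.8)
    ax.set_xlabel(f"pause score, {labels[0]}")
    ax.set_ylabel(f"pause score, {labels[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
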