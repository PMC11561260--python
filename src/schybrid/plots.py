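"""Optional figure output: ECDF curves, overlap heatmaps, bias maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .plasticity import ECDFCurve, FateBiasResult, OverlapMatrix


def plot_ecdf(curve: ECDFCurve, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, vals in curve.values.items():
        ax.step(vals, curve.cumulative[group], where="post", label=group)
    ax.axvline(curve.threshold, linestyle="--", color="black", linewidth=0.8)
    ax.set_xlabel(f"Prob. {curve.target_type}")
    ax.set_ylabel("cumulative fraction")
    ax.set_xlim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_overlap(om: OverlapMatrix, path: str | Path) -> Path:
    mat = om.matrix
    fig, ax = plt.subplots(figsize=(1 + 0.6 * mat.shape[1], 1 + 0.6 * mat.shape[0]))
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("reference")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=6, color="white")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_bias_map(result: FateBiasResult, coords: np.ndarray, path: str | Path,
                  background: np.ndarray | None = None) -> Path:
    """Bias values over user-supplied 2D embedding coordinates."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if background is not None:
        ax.scatter(background[:, 0], background[:, 1], s=3, c="lightgray")
    sc = ax.scatter(coords[:, 0], coords[:, 1], s=4, c=result.bias,
                    cmap="coolwarm", vmin=0, vmax=1)
    fig.colorbar(sc, ax=ax, label=f"bias {result.type_a} vs {result.type_b}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
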