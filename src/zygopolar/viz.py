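"""Cosmetic figure output: profile heatmap and importance boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["save_heatmap", "save_importance_boxplot"]


def save_heatmap(matrix, compartment, path) -> None:
    """Positions × features heatmap with the boundary marked."""
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.axhline(compartment.boundary_index - 0.5, color="white", ls="--", lw=1)
    ax.set_xlabel("feature (probe × T × replicate)")
    ax.set_ylabel("position (0 = tip)")
    fig.colorbar(im, ax=ax, label="z-scored intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_importance_boxplot(classification, path) -> None:
    """Per-structure mean-decrease-Gini (%) boxplot, one point per replicate."""
    df = classification.importance_by_structure
    probes = sorted(df["probe"].unique())
    data = [df.loc[df["probe"] == p, "importance_pct"] for p in probes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=probes)
    ax.set_ylabel("mean decrease in Gini (%)")
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
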