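"""Matplotlib views of profiles: rarefaction curves and abundance heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_rarefaction(curves: dict[str, pd.DataFrame], out_path=None):
    """One rarefaction line per library: depth vs mean detected genomes."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for library, df in sorted(curves.items()):
        ax.plot(df["depth"], df["mean_detected"], marker="o", label=library)
    ax.set_xlabel("subsampled reads")
    ax.set_ylabel("genomes detected (>= 10x)")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_abundance_heatmap(abundance: pd.DataFrame, out_path=None):
    """Taxon x library relative-abundance heatmap (percent)."""
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(abundance) + 2))
    im = ax.imshow(abundance.fillna(0.0).values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(abundance.columns)), abundance.columns)
    ax.set_yticks(range(len(abundance.index)), abundance.index)
    fig.colorbar(im, ax=ax, label="relative abundance (%)")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
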