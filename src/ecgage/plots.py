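"""Figure rendering for the explainability outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .age_groups import group_label


def plot_aggregated_beats(aggregated: dict, fs: float, window_before_ms: float, path: str) -> None:
    """Panel per age group: mean beat colour-mapped by saliency, the top-k
    salient timesteps marked in red, subject/heartbeat counts in the title."""
    groups = sorted(aggregated)
    n = len(groups)
    ncols = min(5, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    for ax, g in zip(axes.ravel(), groups):
        agg = aggregated[g]
        t = (np.arange(len(agg.waveform)) - window_before_ms / 1000.0 * fs) / fs * 1000.0
        sal = agg.saliency
        smax = sal.max() if sal.max() > 0 else 1.0
        ax.scatter(t, agg.waveform, c=sal / smax, cmap="viridis", s=6)
        ax.scatter(t[agg.marked], agg.waveform[agg.marked], color="red", s=18, zorder=3)
        ax.set_title(
            f"{group_label(g)}y  subjects: {agg.n_subjects}  heartbeats: {agg.n_heartbeats}",
            fontsize=8,
        )
        ax.set_xlabel("ms from R peak", fontsize=7)
        ax.set_ylabel("mV", fontsize=7)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_per_group_auc(per_group_auc: dict, path: str) -> None:
    """Bar chart of one-vs-rest AUC per age group."""
    groups = sorted(per_group_auc)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar([group_label(g) for g in groups], [per_group_auc[g] for g in groups])
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
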