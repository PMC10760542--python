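"""Comparison figures: mean±SEM bars plus per-animal swarm points.

One panel per metric, mirroring the usual presentation of per-animal puncta
metrics: a bar at the group mean with an SEM error bar, overlaid with
jittered per-animal points so the raw distribution stays visible.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

METRIC_LABELS = {
    "mean_peak_to_bead": "Puncta intensity (peak-to-bead)",
    "mean_fwhm_um": "Puncta width, FWHM (µm)",
    "density_per_10um": "Puncta density (per 10 µm)",
}


def comparison_figure(
    per_animal: pd.DataFrame,
    wt_genotype: str,
    mut_genotype: str,
    metrics: tuple[str, ...] = tuple(METRIC_LABELS),
    normalize_intensity: bool = True,
    seed: int = 0,
):
    """Build the three-panel group-comparison figure; returns the Figure."""
    rng = np.random.default_rng(seed)
    fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3.4))
    if len(metrics) == 1:
        axes = [axes]
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        groups = []
        for genotype in (wt_genotype, mut_genotype):
            vals = per_animal.loc[per_animal["genotype"] == genotype, metric]
            groups.append(vals.dropna().to_numpy(dtype=float))
        if normalize_intensity and metric == "mean_peak_to_bead" and groups[0].size:
            wt_mean = groups[0].mean()
            groups = [g / wt_mean for g in groups]
        for i, (label, vals) in enumerate(zip((wt_genotype, mut_genotype), groups)):
            if vals.size == 0:
                continue
            mean = vals.mean()
            sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            ax.bar(i, mean, width=0.6, color="0.85", edgecolor="0.3", zorder=1)
            ax.errorbar(i, mean, yerr=sem, fmt="none", ecolor="0.2", capsize=4, zorder=2)
            jitter = rng.uniform(-0.15, 0.15, size=vals.size)
            ax.plot(i + jitter, vals, "o", ms=4, alpha=0.7, zorder=3)
        ax.set_xticks(range(2))
        ax.set_xticklabels((wt_genotype, mut_genotype))
        ax.set_ylabel(METRIC_LABELS.get(metric, metric))
        ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    return fig


def save_comparison_figure(per_animal: pd.DataFrame, wt: str, mut: str, path: str | Path) -> None:
    fig = comparison_figure(per_animal, wt, mut)
    fig.savefig(path, dpi=150)
    plt.close(fig)
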