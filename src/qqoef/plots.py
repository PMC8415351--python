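"""Matplotlib figures for the cohort and longitudinal reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .roi import PHASE_LABELS

__all__ = ["phase_summary_figure", "longitudinal_figure"]


def phase_summary_figure(included: pd.DataFrame, path: str | Path) -> Path:
    """Group mean ± SD of lesion OEF and rOEF across stroke phases."""
    phases = [p for p in PHASE_LABELS if p in set(included["phase"])]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col, label, scale in ((axes[0], "lesion_oef", "OEF (%)", 100.0),
                                  (axes[1], "roef", "rOEF", 1.0)):
        means = [included.loc[included["phase"] == p, col].mean() * scale for p in phases]
        sds = [included.loc[included["phase"] == p, col].std() * scale for p in phases]
        ax.errorbar(range(len(phases)), means, yerr=sds, fmt="o-", capsize=4)
        ax.set_xticks(range(len(phases)))
        ax.set_xticklabels([p.replace("_", "\n") for p in phases], fontsize=8)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def longitudinal_figure(roi_metrics: pd.DataFrame, path: str | Path) -> Path:
    """Relative OEF/CBF of each region across the two scans."""
    metrics = sorted(roi_metrics["metric"].unique())
    fig, axes = plt.subplots(1, len(metrics), figsize=(4.5 * len(metrics), 3.5),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = roi_metrics[roi_metrics["metric"] == metric]
        for region, grp in sub.groupby("region"):
            grp = grp.sort_values("scan")
            ax.plot(grp["scan"], grp["relative"], "o-", label=region)
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("scan")
        ax.set_ylabel(f"relative {metric}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
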