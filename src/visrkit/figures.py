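"""Boxplot summaries of study result tables.

Thin matplotlib helpers producing the cohort-summary figures: DoA by
compression, normalized metric values, and percent-change distributions,
each split by breast-density group.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

METRICS = ("PD", "RE", "RV")


def _grouped_box(ax, df: pd.DataFrame, x_col: str, y_col: str) -> None:
    xs = sorted(df[x_col].unique())
    data_d = [df[(df[x_col] == x) & (df["dense"])][y_col].dropna() for x in xs]
    data_n = [df[(df[x_col] == x) & (~df["dense"])][y_col].dropna() for x in xs]
    pos = range(len(xs))
    bd = ax.boxplot(data_d, positions=[p - 0.18 for p in pos], widths=0.3,
                    patch_artist=True)
    bn = ax.boxplot(data_n, positions=[p + 0.18 for p in pos], widths=0.3,
                    patch_artist=True)
    for box in bd["boxes"]:
        box.set_facecolor("#cc6677")
    for box in bn["boxes"]:
        box.set_facecolor("#88ccee")
    ax.set_xticks(list(pos))
    ax.set_xticklabels([str(x) for x in xs])


def metric_panel_boxplots(
    df: pd.DataFrame,
    x_col: str,
    y_col: str,
    title: str,
    out_path: str | Path,
) -> Path:
    """One panel per metric (PD, RE, RV); dense vs non-dense side by side."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.4), sharey=False)
    for ax, metric in zip(axes, METRICS):
        _grouped_box(ax, df[df["metric"] == metric], x_col, y_col)
        ax.set_title(metric)
        ax.set_xlabel(x_col)
    axes[0].set_ylabel(y_col)
    fig.suptitle(f"{title} (dense = red, non-dense = blue)")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def study_figures(results, out_dir: str | Path) -> list[Path]:
    """Render the standard set of cohort figures from a StudyResults."""
    out = Path(out_dir)
    made = []
    if len(results.doa):
        made.append(metric_panel_boxplots(
            results.doa, "compression_mm", "doa", "DoA under compression",
            out / "doa_by_compression.png"))
    if len(results.doa_pct_change):
        made.append(metric_panel_boxplots(
            results.doa_pct_change, "pair", "pct_change_doa",
            "Percent change in DoA", out / "doa_pct_change.png"))
    if len(results.normalized):
        made.append(metric_panel_boxplots(
            results.normalized, "compression_mm", "normalized",
            "Values normalized to 0 mm", out / "normalized_values.png"))
    if len(results.pct_change_all):
        made.append(metric_panel_boxplots(
            results.pct_change_all, "pair", "pct_change",
            "Percent change (angle-averaged)", out / "pct_change_all.png"))
    return made
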