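"""Static plot exports for pipeline output tables.

All plots read the CSV tables a pipeline run wrote, so they can be
regenerated without recomputation.  Kernel-density (violin) rendering is
presentation: the library's contract is the exported raw distributions,
and the violin/strip plots here are drawn from those tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_suite", "metric_heatmap"]

_METRICS = ("p_value", "peak_count", "area_left")


def metric_heatmap(
    metrics: pd.DataFrame, region_index: int, metric: str, unit_ids: list[str]
):
    """N x N heatmap of one metric in one region; blanks for sparse cells."""
    sub = metrics[metrics["region_index"] == region_index]
    n = len(unit_ids)
    pos = {u: i for i, u in enumerate(unit_ids)}
    grid = np.full((n, n), np.nan)
    for row in sub.itertuples():
        if not row.sparse_flag and row.ref_id in pos and row.cmp_id in pos:
            grid[pos[row.ref_id], pos[row.cmp_id]] = getattr(row, metric)
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(grid, cmap="viridis", interpolation="nearest")
    ax.set_xlabel("comparison unit")
    ax.set_ylabel("reference unit")
    ax.set_title(f"{metric}, region {region_index}")
    fig.colorbar(im, ax=ax)
    return fig


def _violin(ax, metrics: pd.DataFrame, metric: str) -> None:
    groups, labels = [], []
    for region_index, sub in metrics.groupby("region_index"):
        vals = sub.loc[~sub["sparse_flag"], metric].dropna().to_numpy(float)
        if vals.size:
            groups.append(vals)
            labels.append(str(region_index))
    if not groups:
        return
    ax.violinplot(groups, showmedians=True)
    rng = np.random.default_rng(0)  # presentation-only strip-dot jitter
    for i, vals in enumerate(groups, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, vals.size), vals, ".",
                ms=2, color="k", alpha=0.4)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_xlabel("analysis region")
    ax.set_ylabel(metric)


def plot_suite(tables_dir: str | Path, unit_ids: list[str]) -> list[Path]:
    """Render the standard figure set from a pipeline output directory.

    Per-region metric heatmaps, violin+strip metric distributions,
    class-fraction traces, transition matrices and combo heatmaps.
    Missing tables are skipped with a warning.
    """
    tables_dir = Path(tables_dir)
    out: list[Path] = []

    def save(fig, name: str) -> None:
        path = tables_dir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        out.append(path)

    metrics_path = tables_dir / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        for region_index in sorted(metrics["region_index"].unique()):
            for metric in _METRICS:
                fig = metric_heatmap(metrics, region_index, metric, unit_ids)
                save(fig, f"heatmap_{metric}_region{region_index}.png")
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        for ax, metric in zip(axes, _METRICS):
            _violin(ax, metrics, metric)
        fig.tight_layout()
        save(fig, "metric_distributions.png")
    else:
        import warnings

        warnings.warn("metrics.csv missing; metric plots skipped")

    fractions_path = tables_dir / "fractions.csv"
    if fractions_path.exists():
        fractions = pd.read_csv(fractions_path)
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        for ax, scheme in zip(axes, fractions["scheme"].unique()):
            sub = fractions[fractions["scheme"] == scheme]
            for cls, grp in sub.groupby("class"):
                ax.plot(grp["region_index"], grp["fraction"], marker="o", label=str(cls))
            ax.set_title(scheme)
            ax.set_xlabel("analysis region")
            ax.set_ylabel("fraction")
            ax.legend(fontsize=7)
        fig.tight_layout()
        save(fig, "class_fractions.png")

    for trans_path in sorted(tables_dir.glob("transitions_*.csv")):
        trans = pd.read_csv(trans_path)
        for (scheme, grouping), sub in trans.groupby(["scheme", "grouping"]):
            mat = sub.pivot(index="from_class", columns="to_class", values="probability")
            fig, ax = plt.subplots(figsize=(4.2, 3.8))
            im = ax.imshow(mat.to_numpy(float), vmin=0, vmax=1, cmap="magma")
            ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
            ax.set_yticks(range(len(mat.index)), mat.index)
            ax.set_title(f"{scheme} transitions: {grouping}", fontsize=9)
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            safe = str(grouping).replace(":", "_").replace("->", "to")
            save(fig, f"transitions_{scheme}_{safe}.png")

    combos_path = tables_dir / "combos.csv"
    if combos_path.exists():
        combos = pd.read_csv(combos_path)
        value_cols = [c for c in combos.columns
                      if c not in ("uniformity_class", "lf_class", "peak_class")]
        fig, ax = plt.subplots(figsize=(6, max(4, 0.12 * len(combos))))
        im = ax.imshow(combos[value_cols].to_numpy(float), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(value_cols)), value_cols, rotation=45, ha="right")
        ax.set_yticks(
            range(len(combos)),
            [f"{u}/{l}/{p}" for u, l, p in zip(
                combos["uniformity_class"], combos["lf_class"], combos["peak_class"])],
            fontsize=5,
        )
        ax.set_title("combined classification (% of correlograms)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        save(fig, "combo_heatmap.png")

    return out
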