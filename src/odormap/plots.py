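"""Figure emission: component planes, cluster maps, daily-share bars,
per-cluster boxplots, sector roses, and hit maps.

All functions write straight to file using the Agg backend; light shades are
low values and dark shades high ones on the grayscale planes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import Partition
from .fusion import ClusterSummary, DailyShareTable
from .som import SomModel, component_plane


def plot_component_planes(model: SomModel, channel_names, path) -> None:
    n = model.n_channels
    ncols = min(5, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        if i >= n:
            ax.axis("off")
            continue
        plane = component_plane(model, i)
        ax.imshow(plane, cmap="Greys", origin="lower", aspect="auto")
        ax.set_title(channel_names[i], fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cluster_map(model: SomModel, partition: Partition, path) -> None:
    grid = model.grid
    labels = partition.labels.reshape(grid.ydim, grid.xdim)
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(labels, cmap="tab10", origin="lower", aspect="auto",
                   vmin=1, vmax=max(10, partition.k))
    ax.set_title(f"cluster map (k={partition.k})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, ticks=range(1, partition.k + 1), label="cluster")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_daily_shares(daily: DailyShareTable, path) -> None:
    df = daily.data
    fig, ax = plt.subplots(figsize=(max(8, len(df) * 0.12), 3.5))
    bottom = np.zeros(len(df))
    x = np.arange(len(df))
    for c in range(1, daily.k + 1):
        vals = df[f"share_{c}"].fillna(0.0).to_numpy()
        ax.bar(x, vals, bottom=bottom, width=0.9, label=f"cluster {c}")
        bottom += vals
    for i, nd in enumerate(df["nd_flag"].to_numpy()):
        if nd:
            ax.text(i, 50, "ND", rotation=90, ha="center", va="center", fontsize=6)
    ax.set_xticks(x[::7])
    ax.set_xticklabels([d.strftime("%m-%d") for d in df.index[::7]], rotation=90, fontsize=6)
    ax.set_ylabel("% of recorded minutes")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=7, ncol=daily.k)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_cluster_boxplots(model: SomModel, partition: Partition, channel_names, path) -> None:
    from .som import normalize_invert

    weights = normalize_invert(model.norm, model.codebook)
    k = partition.k
    fig, axes = plt.subplots(1, model.n_channels, figsize=(1.6 * model.n_channels, 3),
                             sharey=False)
    for i, ax in enumerate(np.atleast_1d(axes)):
        groups = [weights[partition.labels == c + 1, i] for c in range(k)]
        ax.boxplot(groups, tick_labels=[str(c + 1) for c in range(k)])
        ax.set_title(channel_names[i], fontsize=7)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sector_rose(summary: ClusterSummary, cluster: int, path) -> None:
    freq = summary.sector_freq.loc[cluster]
    n = len(freq)
    theta = np.deg2rad(np.arange(n) * 360.0 / n)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(theta, freq.to_numpy(), width=2 * np.pi / n * 0.9)
    ax.set_xticks(theta)
    ax.set_xticklabels(freq.index, fontsize=7)
    ax.set_title(f"wind sector frequency, cluster {cluster} (%)", fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_hit_map(model: SomModel, hits: np.ndarray, path, title: str = "BMU hits") -> None:
    grid = model.grid
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(hits.reshape(grid.ydim, grid.xdim), cmap="Greys",
                   origin="lower", aspect="auto")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="minutes")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def emit_all(stage1, stage2, meta, outdir) -> list[Path]:
    """Write the standard figure set for a completed two-stage run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(meta.names.get(s, s) for s in meta.sensor_ids)
    out = []

    def _p(name):
        p = outdir / name
        out.append(p)
        return p

    plot_component_planes(stage1.model, names, _p("stage1_planes.png"))
    plot_cluster_map(stage1.model, stage1.selection.best_partition,
                     _p("stage1_cluster_map.png"))
    plot_daily_shares(stage1.daily, _p("stage1_daily_shares.png"))
    plot_component_planes(stage2.model, names, _p("stage2_planes.png"))
    plot_cluster_map(stage2.model, stage2.selection.best_partition,
                     _p("stage2_cluster_map.png"))
    plot_daily_shares(stage2.daily, _p("stage2_daily_shares.png"))
    plot_cluster_boxplots(stage2.model, stage2.selection.best_partition, names,
                          _p("stage2_cluster_boxplots.png"))
    for c in range(1, stage2.selection.best_k + 1):
        plot_sector_rose(stage2.summary, c, _p(f"stage2_sector_rose_c{c}.png"))
    if stage2.external_hits is not None:
        plot_hit_map(stage2.model, stage2.external_hits,
                     _p("external_hit_map.png"), title="external BMU hits")
    return out
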