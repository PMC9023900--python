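"""The two signature displays: pooled-importance bars and loss-coloured violins.

All plotting data pass through small, testable prep steps:
:func:`violin_prep` bins each variable's cloud values (merging empty edge
bins toward the violin centre) and attaches the mean model loss per bin;
:meth:`ViolinSummary.geometry` converts bins into the mirrored slices that
are actually drawn, normalised so every violin encloses the same area.
Rendered output is deterministic given the data (fixed SVG hash salt, no
embedded timestamps), so re-running a pipeline reproduces byte-identical
vector files.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors as mcolors

from .shapley import ImportanceCloud

__all__ = ["ViolinSummary", "violin_prep", "bar_plot", "violin_plot"]

plt.rcParams["svg.hashsalt"] = "shapleyvic"

_CMAP = "viridis"


@dataclass
class ViolinSummary:
    """Binned cloud values per variable, with per-bin mean model loss."""

    variables: list[str]
    bins: dict[str, pd.DataFrame]  # columns: lo, hi, count, proportion, mean_loss
    merged: dict[str, int]  # number of empty-bin merges per variable

    def __post_init__(self) -> None:
        for name in self.variables:
            df = self.bins[name]
            if not np.isclose(df["proportion"].sum(), 1.0):
                raise ValueError(f"proportions for {name!r} do not sum to 1")
            if (df["count"] == 0).any():
                raise ValueError(f"empty bin retained for {name!r}")

    def geometry(self, area: float = 0.3) -> dict[str, pd.DataFrame]:
        """Slice rectangles per variable: half-heights are densities scaled
        so every violin encloses exactly ``2 * area`` (mirrored)."""
        out = {}
        for name in self.variables:
            df = self.bins[name].copy()
            width = (df["hi"] - df["lo"]).clip(lower=1e-12)
            df["half_height"] = area * df["proportion"] / width
            out[name] = df
        return out


def violin_prep(cloud: ImportanceCloud, n_bins: int = 20) -> ViolinSummary:
    """Equal-width binning of each variable's values across the cloud.

    Bins that catch no model are merged with the neighbour closer to the
    violin centre, working from the ends inward, so the retained slices
    partition the value range without gaps.
    """
    if cloud.m == 0:
        raise ValueError("empty cloud")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = cloud.values
    losses = cloud.losses
    bins: dict[str, pd.DataFrame] = {}
    merged: dict[str, int] = {}
    for j, name in enumerate(cloud.names):
        v = values[:, j]
        lo, hi = float(v.min()), float(v.max())
        if np.isclose(lo, hi):
            bins[name] = pd.DataFrame(
                {
                    "lo": [lo],
                    "hi": [hi if hi > lo else lo + 1e-12],
                    "count": [len(v)],
                    "proportion": [1.0],
                    "mean_loss": [float(losses.mean())],
                }
            )
            merged[name] = 0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)
        rows = [
            {
                "lo": edges[k],
                "hi": edges[k + 1],
                "count": int(np.sum(idx == k)),
                "loss_sum": float(losses[idx == k].sum()),
            }
            for k in range(n_bins)
        ]
        merged[name] = _merge_empty(rows, centre=(lo + hi) / 2)
        df = pd.DataFrame(rows)
        df["proportion"] = df["count"] / len(v)
        df["mean_loss"] = df["loss_sum"] / df["count"]
        bins[name] = df.drop(columns="loss_sum")
    return ViolinSummary(variables=list(cloud.names), bins=bins, merged=merged)


def _merge_empty(rows: list[dict], centre: float) -> int:
    """Merge empty bins into the neighbour closer to ``centre`` (in place)."""
    n_merges = 0
    while len(rows) > 1:
        empties = [k for k, r in enumerate(rows) if r["count"] == 0]
        if not empties:
            break
        # work from the ends inward: treat the empty bin farthest from centre
        k = max(
            empties, key=lambda k: abs((rows[k]["lo"] + rows[k]["hi"]) / 2 - centre)
        )
        bin_centre = (rows[k]["lo"] + rows[k]["hi"]) / 2
        into = k + 1 if (bin_centre < centre and k + 1 < len(rows)) else k - 1
        if into < 0:
            into = k + 1
        lo = min(rows[k]["lo"], rows[into]["lo"])
        hi = max(rows[k]["hi"], rows[into]["hi"])
        rows[into].update(
            lo=lo,
            hi=hi,
            count=rows[into]["count"] + rows[k]["count"],
            loss_sum=rows[into]["loss_sum"] + rows[k]["loss_sum"],
        )
        del rows[k]
        n_merges += 1
    return n_merges


def _save(fig, path) -> None:
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def bar_plot(pooled: pd.DataFrame, path) -> None:
    """Horizontal bars of pooled means with 95% prediction-interval whiskers.

    Bars keep the (descending-mean) order of the pooled table; variables
    whose interval straddles zero are drawn de-emphasised (grey) since
    their overall importance is not significant.
    """
    if pooled.empty:
        raise ValueError("empty pooled table")
    df = pooled.reset_index(drop=True)
    y = np.arange(len(df))[::-1]  # most important on top
    colours = ["#3b6ea5" if s else "#bbbbbb" for s in df["significant"]]
    err = np.vstack(
        [df["mean"] - df["pi_lower"], df["pi_upper"] - df["mean"]]
    )
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(df) + 1.5))
    ax.barh(y, df["mean"], xerr=err, color=colours, capsize=3, height=0.6)
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(df["variable"])
    ax.set_xlabel("average model reliance (95% prediction interval)")
    handles = [
        plt.Rectangle((0, 0), 1, 1, color="#3b6ea5"),
        plt.Rectangle((0, 0), 1, 1, color="#bbbbbb"),
    ]
    ax.legend(handles, ["significant", "not significant (PI contains 0)"],
              loc="lower right", fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def violin_plot(
    summary: ViolinSummary,
    loss_range: tuple[float, float],
    path,
) -> None:
    """Mirrored loss-coloured slices, one violin per variable.

    Slice colour encodes the mean empirical loss of the models in the
    slice on a colour scale shared across variables.
    """
    vmin, vmax = loss_range
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
    cmap = plt.get_cmap(_CMAP)
    geom = summary.geometry()
    fig, ax = plt.subplots(
        figsize=(7, 0.8 * len(summary.variables) + 1.5)
    )
    # one global scale so violins keep equal areas relative to each other
    scale = 0.42 / max(
        max(geom[n]["half_height"].max() for n in summary.variables), 1e-12
    )
    for i, name in enumerate(summary.variables):
        df = geom[name]
        for _, row in df.iterrows():
            h = row["half_height"] * scale
            ax.fill_between(
                [row["lo"], row["hi"]], i - h, i + h,
                color=cmap(norm(row["mean_loss"])), lw=0,
            )
    ax.set_yticks(range(len(summary.variables)))
    ax.set_yticklabels(summary.variables)
    ax.set_xlabel("model reliance")
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label="empirical loss")
    fig.tight_layout()
    _save(fig, path)
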