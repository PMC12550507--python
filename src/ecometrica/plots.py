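"""Ecometric-space visualisation.

All plots share one geometry: the trait grid with metric1 on the x axis and
metric2 on the y axis, one rectangle per non-empty bin. Fills are the bin's
predicted category, per-category probability, or continuous estimate; empty
(and zero-probability) bins are left transparent. When reconstructions are
supplied, fossil bins are outlined (black by default) and nearest-analogue
bins outlined in a second colour (red by default).

Every figure is backed by a ``PlotSpec`` capturing the drawn data layer, so
identical model + reconstruction inputs yield identical specs regardless of
rendering backend; tests compare specs, not pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.patches import Rectangle

from .models import CategoricalModel, ContinuousModel

DEFAULT_FOSSIL_COLOR = "black"
DEFAULT_ANALOGUE_COLOR = "red"


@dataclass
class PlotSpec:
    """Pure-data description of one ecometric-space panel."""

    kind: str  # "category" | "probability" | "continuous"
    edges1: list[float]
    edges2: list[float]
    cells: dict = field(default_factory=dict)  # (i, j) -> fill value
    outlines: list = field(default_factory=list)  # (i, j, which) with which in {fossil, analogue}
    x_label: str = "metric1"
    y_label: str = "metric2"
    title: str = ""


def _outline_layers(recon: pd.DataFrame | None) -> list[tuple[int, int, str]]:
    if recon is None or len(recon) == 0:
        return []
    out = []
    for row in recon.itertuples():
        out.append((int(row.bin_i), int(row.bin_j), "fossil"))
        ai = getattr(row, "analogue_bin_i", None)
        aj = getattr(row, "analogue_bin_j", None)
        if ai is not None and aj is not None and not (pd.isna(ai) or pd.isna(aj)):
            out.append((int(ai), int(aj), "analogue"))
    # deterministic order, no duplicates
    return sorted(set(out))


def _draw(spec: PlotSpec, fill_color, fossil_color, analogue_color, colorbar=None):
    e1, e2 = spec.edges1, spec.edges2
    fig, ax = plt.subplots(figsize=(6, 5))
    for (i, j), val in spec.cells.items():
        ax.add_patch(
            Rectangle(
                (e1[i], e2[j]),
                e1[i + 1] - e1[i],
                e2[j + 1] - e2[j],
                facecolor=fill_color(val),
                edgecolor="none",
            )
        )
    for i, j, which in spec.outlines:
        ax.add_patch(
            Rectangle(
                (e1[i], e2[j]),
                e1[i + 1] - e1[i],
                e2[j + 1] - e2[j],
                facecolor="none",
                edgecolor=fossil_color if which == "fossil" else analogue_color,
                linewidth=1.6,
            )
        )
    ax.set_xlim(e1[0], e1[-1])
    ax.set_ylim(e2[0], e2[-1])
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.set_title(spec.title)
    if colorbar is not None:
        fig.colorbar(colorbar, ax=ax)
    fig.tight_layout()
    return fig


def plot_category_space(
    model: CategoricalModel,
    recon: pd.DataFrame | None = None,
    x_label: str = "Community trait mean",
    y_label: str = "Community trait SD",
    fossil_color: str = DEFAULT_FOSSIL_COLOR,
    analogue_color: str = DEFAULT_ANALOGUE_COLOR,
    path=None,
):
    """Category map: each non-empty bin coloured by its predicted category."""
    spec = PlotSpec(
        kind="category",
        edges1=[float(v) for v in model.grid.edges1],
        edges2=[float(v) for v in model.grid.edges2],
        x_label=x_label,
        y_label=y_label,
        title=f"Predicted {model.env_col}",
    )
    for i in range(model.grid.b1):
        for j in range(model.grid.b2):
            if model.predicted[i, j] is not None:
                spec.cells[(i, j)] = model.predicted[i, j]
    spec.outlines = _outline_layers(recon)

    cmap = colormaps["tab10"]
    color_of = {c: cmap(k % 10) for k, c in enumerate(model.categories)}
    fig = _draw(spec, lambda v: color_of[v], fossil_color, analogue_color)
    handles = [plt.Line2D([], [], marker="s", ls="", color=color_of[c], label=c)
               for c in model.categories]
    fig.axes[0].legend(handles=handles, fontsize=8, loc="upper right")
    if path is not None:
        fig.savefig(path)
    return fig, spec


def plot_probability_maps(
    model: CategoricalModel,
    recon: pd.DataFrame | None = None,
    x_label: str = "Community trait mean",
    y_label: str = "Community trait SD",
    fossil_color: str = DEFAULT_FOSSIL_COLOR,
    analogue_color: str = DEFAULT_ANALOGUE_COLOR,
    out_dir=None,
):
    """One probability panel per category.

    Fill is the probability that a bin belongs to the category; bins with
    zero probability (and empty bins) are transparent.
    """
    outlines = _outline_layers(recon)
    cmap = colormaps["viridis"]
    figs, specs = [], []
    for k, cat in enumerate(model.categories):
        spec = PlotSpec(
            kind="probability",
            edges1=[float(v) for v in model.grid.edges1],
            edges2=[float(v) for v in model.grid.edges2],
            x_label=x_label,
            y_label=y_label,
            title=f"P({model.env_col} = {cat})",
        )
        for i in range(model.grid.b1):
            for j in range(model.grid.b2):
                p = model.prob[i, j, k]
                if np.isfinite(p) and p > 0:
                    spec.cells[(i, j)] = float(p)
        spec.outlines = outlines
        sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 1))
        fig = _draw(spec, lambda v: cmap(v), fossil_color, analogue_color, colorbar=sm)
        if out_dir is not None:
            fig.savefig(f"{out_dir}/probability_{cat}.png")
        figs.append(fig)
        specs.append(spec)
    return figs, specs


def plot_continuous_space(
    model: ContinuousModel,
    recon: pd.DataFrame | None = None,
    x_label: str = "Community trait mean",
    y_label: str = "Community trait SD",
    fossil_color: str = DEFAULT_FOSSIL_COLOR,
    analogue_color: str = DEFAULT_ANALOGUE_COLOR,
    path=None,
):
    """Continuous map: non-empty bins coloured by their ML environmental estimate."""
    spec = PlotSpec(
        kind="continuous",
        edges1=[float(v) for v in model.grid.edges1],
        edges2=[float(v) for v in model.grid.edges2],
        x_label=x_label,
        y_label=y_label,
        title=f"Predicted {model.env_col}",
    )
    for i in range(model.grid.b1):
        for j in range(model.grid.b2):
            v = model.predicted[i, j]
            if np.isfinite(v):
                spec.cells[(i, j)] = float(v)
    spec.outlines = _outline_layers(recon)

    vals = list(spec.cells.values())
    vmin, vmax = (min(vals), max(vals)) if vals else (0.0, 1.0)
    cmap = colormaps["viridis"]
    norm = plt.Normalize(vmin, vmax) if vmax > vmin else plt.Normalize(vmin - 1, vmax + 1)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
    fig = _draw(spec, lambda v: cmap(norm(v)), fossil_color, analogue_color, colorbar=sm)
    if path is not None:
        fig.savefig(path)
    return fig, spec
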