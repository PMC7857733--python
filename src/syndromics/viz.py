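"""Publication plots for component interpretation.

Four views of a loading solution:

* **syndromic plot** — one figure per component: a central triangle
  annotated with the component's VAF and one radial arrow per variable
  whose |loading| exceeds the (required, user-chosen) cutoff.  Arrow
  width and color saturation are proportional to |loading|; color
  encodes sign on a diverging scale (blue = +1, white = 0, red = -1).
  Arrows are evenly spaced angularly, ordered by descending |loading|
  clockwise from 12 o'clock.
* **loading heatmap** — variables x components grid on the same
  diverging scale, with optional stars on cells exceeding a (possibly
  per-component) cutoff and optional numeric cell text.
* **barmaps** — horizontal bars of loadings (any subset of components)
  or communalities, with optional resampling error bars and cutoff guide
  lines.
* **VAF plot** — scree-style line of all components' VAF ('line') or the
  retained ones only ('reduced'), with an optional permutation-null
  ribbon.

Vector output (SVG/PDF) is the primary target; rendering is
deterministic (timestamps and hash salts pinned) so identical inputs
produce identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import matplotlib as mpl
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import FancyArrow, Polygon

from .pca import LoadingsTable

__all__ = [
    "PlotSpec",
    "loading_color",
    "select_salient",
    "salient_mask",
    "syndromic_plot",
    "heatmap_loadings",
    "barmap_loadings",
    "barmap_commun",
    "vaf_plot",
    "save_figure",
]

_CMAP = "RdBu"  # matplotlib diverging map: 0 -> red, 0.5 -> white, 1 -> blue


@dataclass(frozen=True)
class PlotSpec:
    """Shared plot settings.

    ``cutoff`` is the |loading| threshold — scalar, or one value per
    plotted component for the heatmap.  ``ndim`` selects components:
    an integer keeps the first ndim, a sequence selects explicit 1-based
    component numbers.  ``vaf_labels`` are per-PC percent strings such
    as ``"32.9%"`` (required by the syndromic plot when the VAF cannot
    be derived from the input).
    """

    cutoff: float | Sequence[float] | None = None
    ndim: int | Sequence[int] | None = None
    vaf_labels: Sequence[str] | None = None
    star_values: bool = True
    text_values: bool = False
    figsize: tuple[float, float] | None = None

    def __post_init__(self):
        if self.cutoff is not None:
            c = np.atleast_1d(np.asarray(self.cutoff, dtype=float))
            if np.any(c < 0):
                raise ValueError("cutoff must be >= 0")


def loading_color(loading: float) -> tuple[float, float, float, float]:
    """Diverging color for one loading: -1 -> saturated red, 0 -> white,
    +1 -> saturated blue."""
    return mpl.colormaps[_CMAP]((float(loading) + 1) / 2)


def select_salient(
    loadings: LoadingsTable, cutoff: float, component: str | int
) -> pd.DataFrame:
    """Variables with |loading| > cutoff on one component, sorted by
    descending |loading| (the syndromic plot's arrow order).  Shared by the
    plotting code and the test suite."""
    col = loadings.column(component)
    mask = np.abs(col) > cutoff
    frame = pd.DataFrame(
        {"Variable": np.asarray(loadings.variables)[mask], "Loading": col[mask]}
    )
    frame["absLoading"] = frame["Loading"].abs()
    frame = frame.sort_values(
        ["absLoading", "Variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return frame


def salient_mask(loadings: LoadingsTable, cutoff: float | Sequence[float]) -> np.ndarray:
    """Boolean (v, k) mask of |loading| > cutoff, with a scalar cutoff or
    one cutoff per component (the heatmap's star positions)."""
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if cut.size == 1:
        cut = np.full(loadings.k, cut[0])
    if cut.size != loadings.k:
        raise ValueError(
            f"per-component cutoff length {cut.size} does not match {loadings.k} components"
        )
    return np.abs(loadings.values) > cut[None, :]


def _selected_components(loadings: LoadingsTable, ndim) -> list[str]:
    if ndim is None:
        return list(loadings.components)
    if np.isscalar(ndim):
        return loadings.components[: int(ndim)]
    return [loadings.components[int(j) - 1] for j in ndim]


def _arrow_width(absload: float, cutoff: float) -> float:
    """Linear in |loading| over [cutoff, 1], minimum visible width at the cutoff."""
    wmin, wmax = 0.012, 0.06
    if cutoff >= 1:
        return wmin
    t = np.clip((absload - cutoff) / (1 - cutoff), 0, 1)
    return wmin + t * (wmax - wmin)


def syndromic_plot(
    loadings: LoadingsTable, spec: PlotSpec
) -> dict[str, plt.Figure]:
    """One syndromic-plot figure per plotted component.

    Requires ``spec.cutoff`` (no default: the salience threshold is an
    analytic decision) and ``spec.vaf_labels`` with one entry per plotted
    component.
    """
    if spec.cutoff is None:
        raise ValueError("syndromic_plot requires a cutoff (no default)")
    cutoff = float(np.atleast_1d(spec.cutoff)[0])
    components = _selected_components(loadings, spec.ndim)
    if spec.vaf_labels is None:
        raise ValueError("syndromic_plot requires vaf_labels (e.g. ['32.9%', ...])")
    if len(spec.vaf_labels) < len(components):
        raise ValueError(
            f"need {len(components)} VAF labels, got {len(spec.vaf_labels)}"
        )
    figures: dict[str, plt.Figure] = {}
    for idx, pc in enumerate(components):
        sel = select_salient(loadings, cutoff, pc)
        fig, ax = plt.subplots(figsize=spec.figsize or (7, 7))
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_xlim(-1.45, 1.45)
        ax.set_ylim(-1.45, 1.45)
        # central convex triangle carrying the VAF annotation
        tri_r = 0.32
        angles = np.deg2rad([90, 210, 330])
        tri = Polygon(
            np.column_stack([tri_r * np.cos(angles), tri_r * np.sin(angles)]),
            closed=True,
            facecolor="0.92",
            edgecolor="0.2",
            linewidth=1.2,
            zorder=3,
        )
        ax.add_patch(tri)
        ax.text(0, -0.02, spec.vaf_labels[idx], ha="center", va="center",
                fontsize=13, zorder=4)
        ax.text(0, 1.32, pc, ha="center", va="center", fontsize=14)
        m = len(sel)
        for i, row in sel.iterrows():
            theta = np.deg2rad(90 - 360 * i / m) if m else 0.0
            ux, uy = np.cos(theta), np.sin(theta)
            r_out, r_in = 1.05, 0.40
            width = _arrow_width(row["absLoading"], cutoff)
            arrow = FancyArrow(
                r_out * ux,
                r_out * uy,
                (r_in - r_out) * ux,
                (r_in - r_out) * uy,
                width=width,
                head_width=width * 2.4,
                head_length=0.07,
                length_includes_head=True,
                facecolor=loading_color(row["Loading"]),
                edgecolor="0.25",
                linewidth=0.6,
                zorder=2,
            )
            ax.add_patch(arrow)
            ax.text(
                1.14 * ux,
                1.14 * uy,
                row["Variable"],
                ha="center",
                va="center",
                fontsize=9,
                rotation=0,
            )
        figures[pc] = fig
    return figures


def heatmap_loadings(loadings: LoadingsTable, spec: PlotSpec) -> plt.Figure:
    """Variables x components heatmap with optional stars and cell text."""
    components = _selected_components(loadings, spec.ndim)
    sub = loadings.retain([loadings.components.index(pc) + 1 for pc in components])
    fig, ax = plt.subplots(figsize=spec.figsize or (2 + 0.9 * sub.k, 0.38 * sub.v + 1.5))
    im = ax.imshow(sub.values, cmap=_CMAP, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(sub.k), sub.components)
    ax.set_yticks(range(sub.v), sub.variables)
    fig.colorbar(im, ax=ax, label="standardized loading")
    if spec.cutoff is not None and spec.star_values:
        mask = salient_mask(sub, spec.cutoff)
        for i, j in zip(*np.nonzero(mask)):
            ax.text(j, i, "*", ha="center", va="center", fontsize=12, color="0.1")
    if spec.text_values:
        for i in range(sub.v):
            for j in range(sub.k):
                ax.text(
                    j,
                    i + 0.28,
                    f"{sub.values[i, j]:.2f}",
                    ha="center",
                    va="center",
                    fontsize=7,
                    color="0.25",
                )
    fig.tight_layout()
    return fig


def _check_errors(errors, values: np.ndarray):
    if errors is None:
        return None
    low, high = (np.asarray(e, dtype=float) for e in errors)
    if low.shape != values.shape or high.shape != values.shape:
        raise ValueError(
            f"error-bar arrays {low.shape}/{high.shape} do not match values {values.shape}"
        )
    return low, high


def barmap_loadings(
    loadings: LoadingsTable,
    spec: PlotSpec,
    errors: tuple[np.ndarray, np.ndarray] | None = None,
) -> plt.Figure:
    """Horizontal loading bars, one panel per selected component.

    ``errors`` is an optional (low, high) pair of arrays aligned with the
    selected loadings (from a bootstrap or permutation run).
    """
    components = _selected_components(loadings, spec.ndim)
    sub = loadings.retain([loadings.components.index(pc) + 1 for pc in components])
    err = _check_errors(errors, sub.values)
    npc = sub.k
    fig, axes = plt.subplots(
        1, npc, figsize=spec.figsize or (3.2 * npc, 0.3 * sub.v + 1.2),
        sharey=True, squeeze=False,
    )
    ypos = np.arange(sub.v)[::-1]
    for j, (pc, ax) in enumerate(zip(sub.components, axes[0])):
        vals = sub.values[:, j]
        ax.barh(ypos, vals, color=[loading_color(x) for x in vals], edgecolor="0.3")
        if err is not None:
            low, high = err
            ax.errorbar(
                (low[:, j] + high[:, j]) / 2,
                ypos,
                xerr=np.vstack(
                    [(low[:, j] + high[:, j]) / 2 - low[:, j],
                     high[:, j] - (low[:, j] + high[:, j]) / 2]
                ),
                fmt="o",
                color="0.15",
                markersize=3,
                linewidth=1,
            )
        if spec.cutoff is not None:
            cut = float(np.atleast_1d(spec.cutoff)[min(j, np.atleast_1d(spec.cutoff).size - 1)])
            ax.axvline(cut, color="0.4", linestyle="--", linewidth=0.8)
            ax.axvline(-cut, color="0.4", linestyle="--", linewidth=0.8)
        ax.axvline(0, color="0.2", linewidth=0.8)
        ax.set_xlim(-1.05, 1.05)
        ax.set_title(pc)
    axes[0][0].set_yticks(ypos, sub.variables)
    fig.tight_layout()
    return fig


def barmap_commun(
    communalities: pd.Series,
    spec: PlotSpec | None = None,
    errors: tuple[np.ndarray, np.ndarray] | None = None,
) -> plt.Figure:
    """Horizontal communality bars (values in [0, 1]) with optional error bars."""
    spec = spec or PlotSpec()
    h = np.asarray(communalities.to_numpy(), dtype=float)
    if np.any(h < 0):
        raise ValueError("communalities cannot be negative")
    if np.any(h > 1 + 1e-9):
        raise ValueError("communalities cannot exceed 1")
    err = _check_errors(errors, h)
    fig, ax = plt.subplots(figsize=spec.figsize or (5, 0.3 * h.size + 1.2))
    ypos = np.arange(h.size)[::-1]
    ax.barh(ypos, h, color="#5b84b1", edgecolor="0.3")
    if err is not None:
        low, high = err
        ax.errorbar(
            (low + high) / 2,
            ypos,
            xerr=np.vstack([(low + high) / 2 - low, high - (low + high) / 2]),
            fmt="o",
            color="0.15",
            markersize=3,
            linewidth=1,
        )
    ax.set_yticks(ypos, list(communalities.index))
    ax.set_xlim(0, 1.02)
    ax.set_xlabel("communality")
    fig.tight_layout()
    return fig


def vaf_plot(
    vaf: np.ndarray,
    style: str = "line",
    ndim: int | None = None,
    null_mean: np.ndarray | None = None,
    null_ci: tuple[np.ndarray, np.ndarray] | None = None,
) -> plt.Figure:
    """Scree-style VAF plot.

    ``style='line'`` shows every component; ``style='reduced'`` only the
    first ``ndim``.  An optional permutation-null overlay draws the null
    mean with a CI ribbon per component.
    """
    if style not in ("line", "reduced"):
        raise ValueError("style must be 'line' or 'reduced'")
    vaf = np.asarray(vaf, dtype=float)
    if style == "reduced":
        if ndim is None:
            raise ValueError("style='reduced' requires ndim")
        vaf = vaf[:ndim]
    x = np.arange(1, vaf.size + 1)
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.plot(x, vaf, "o-", color="#27496d", label="observed VAF")
    if null_mean is not None:
        nm = np.asarray(null_mean, dtype=float)[: vaf.size]
        ax.plot(x[: nm.size], nm, "s--", color="0.45", label="permutation null")
        if null_ci is not None:
            low = np.asarray(null_ci[0], dtype=float)[: nm.size]
            high = np.asarray(null_ci[1], dtype=float)[: nm.size]
            ax.fill_between(x[: nm.size], low, high, color="0.7", alpha=0.4)
        ax.legend()
    ax.set_xticks(x)
    ax.set_xlabel("component")
    ax.set_ylabel("VAF (%)")
    fig.tight_layout()
    return fig


def save_figure(fig: plt.Figure, path: str, format: str | None = None) -> None:
    """Write a figure to SVG or PDF with deterministic (timestamp-free) output."""
    fmt = format or str(path).rsplit(".", 1)[-1].lower()
    if fmt not in ("svg", "pdf"):
        raise ValueError(f"unsupported vector format {fmt!r}; use svg or pdf")
    metadata = {"Date": None} if fmt == "svg" else {"CreationDate": None}
    with mpl.rc_context({"svg.hashsalt": "syndromics"}):
        fig.savefig(path, format=fmt, metadata=metadata)
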