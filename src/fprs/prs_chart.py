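"""PRS_Chart: a compact circular diagram of one range-shift record.

The chart encodes all five indices in a single glyph:

* a unit circle (thin black) is the current range area;
* a concentric circle (broad dashed blue) drawn with *area* proportional
  to the cardinality ratio c(F_f)/c(F_p), i.e. radius = sqrt(ratio), is
  the future range, so the area gap between circles is the range
  increment I;
* a sector of the unit circle (red) whose area fraction equals the
  overlap O, drawn from 12 o'clock sweeping clockwise;
* a horizontal-displacement arrow (blue) pointing along (Dx, Dy), with
  log-scaled length: a 1-degree movement is one chart unit long and a
  10-degree movement two units (length = 1 + log10(d));
* a vertical arrow (black) up or down for Dz on the same rule with a
  100 m unit length.

Movements of 0.1 degree or less (10 m or less vertically) would get
non-positive log lengths; they are clamped to zero and omitted from the
drawing rather than shown as dots.

Rendering is deterministic: fixed geometry produces byte-identical SVG
across runs (matplotlib's hash salt is pinned and volatile metadata
stripped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Wedge

from .prs_indices import PRSIndices

__all__ = [
    "ChartGeometry",
    "ChartStyle",
    "arrow_length",
    "chart_geometry",
    "render_chart",
    "render_panel",
    "HORIZONTAL_UNIT_DEGREES",
    "VERTICAL_UNIT_METERS",
]

#: Movement drawn one chart unit long: 1 degree horizontally, 100 m vertically.
HORIZONTAL_UNIT_DEGREES = 1.0
VERTICAL_UNIT_METERS = 100.0

_SVG_HASHSALT = "fprs-chart"


@dataclass(frozen=True)
class ChartGeometry:
    """Resolved drawing primitives for one chart, in chart units."""

    current_radius: float  # always 1
    future_radius: float
    sector_fraction: float  # = O
    sector_angle: float  # radians, = 2*pi*O
    h_direction: float  # radians CCW from east
    h_length: float  # chart units, 0 when omitted
    v_sign: str  # "up", "down" or "none"
    v_length: float  # chart units


@dataclass(frozen=True)
class ChartStyle:
    """Cosmetic options; defaults follow the reference colour scheme."""

    current_color: str = "black"
    current_lw: float = 1.0
    future_color: str = "tab:blue"
    future_lw: float = 2.5
    sector_color: str = "red"
    h_arrow_color: str = "tab:blue"
    v_arrow_color: str = "black"
    lim: float = 3.2  # half-width of the axes in chart units


def arrow_length(distance: float, unit: float) -> float:
    """Log-scaled arrow length: 1 + log10(distance/unit), clamped at 0.

    ``distance`` and ``unit`` share units (degrees or meters).  A movement
    of one unit maps to length 1, ten units to length 2; anything at or
    below a tenth of a unit maps to 0 (omitted from the drawing).
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    r = distance / unit
    if r <= 0.1:
        return 0.0
    return 1.0 + math.log10(r)


def chart_geometry(idx: PRSIndices, *, radius_mode: str = "area") -> ChartGeometry:
    """Resolve a PRS record into drawing primitives.

    ``radius_mode="area"`` (default) draws the future circle with area
    proportional to the cardinality ratio (radius = sqrt(ratio)), so the
    visual area difference encodes I.  ``radius_mode="radius"`` makes the
    radius itself proportional to the ratio.
    """
    ratio = idx.card_future / idx.card_current
    if radius_mode == "area":
        future_radius = math.sqrt(ratio)
    elif radius_mode == "radius":
        future_radius = ratio
    else:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")

    d = math.hypot(idx.dx, idx.dy)
    h_len = arrow_length(d, HORIZONTAL_UNIT_DEGREES)
    h_dir = math.atan2(idx.dy, idx.dx) if h_len > 0 else 0.0

    v_len = arrow_length(abs(idx.dz), VERTICAL_UNIT_METERS)
    if v_len == 0.0:
        v_sign = "none"
    else:
        v_sign = "up" if idx.dz > 0 else "down"

    o = idx.o_index
    return ChartGeometry(
        current_radius=1.0,
        future_radius=future_radius,
        sector_fraction=o,
        sector_angle=2.0 * math.pi * o,
        h_direction=h_dir,
        h_length=h_len,
        v_sign=v_sign,
        v_length=v_len,
    )


def _draw(ax: matplotlib.axes.Axes, geom: ChartGeometry, style: ChartStyle) -> None:
    # draw order: sector, current circle, future circle, arrows
    if geom.sector_fraction > 0:
        sweep_deg = math.degrees(geom.sector_angle)
        # start at 12 o'clock, sweep clockwise
        ax.add_patch(
            Wedge(
                (0, 0),
                1.0,
                90.0 - sweep_deg,
                90.0,
                facecolor=style.sector_color,
                edgecolor="none",
            )
        )
    ax.add_patch(
        Circle(
            (0, 0),
            geom.current_radius,
            fill=False,
            edgecolor=style.current_color,
            linewidth=style.current_lw,
        )
    )
    if geom.future_radius > 0:
        ax.add_patch(
            Circle(
                (0, 0),
                geom.future_radius,
                fill=False,
                edgecolor=style.future_color,
                linewidth=style.future_lw,
                linestyle=(0, (4, 3)),
            )
        )
    if geom.h_length > 0:
        ax.annotate(
            "",
            xy=(
                geom.h_length * math.cos(geom.h_direction),
                geom.h_length * math.sin(geom.h_direction),
            ),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", color=style.h_arrow_color, lw=1.6),
        )
    if geom.v_length > 0 and geom.v_sign != "none":
        tip = geom.v_length if geom.v_sign == "up" else -geom.v_length
        ax.annotate(
            "",
            xy=(0, tip),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", color=style.v_arrow_color, lw=1.4),
        )
    ax.set_xlim(-style.lim, style.lim)
    ax.set_ylim(-style.lim, style.lim)
    ax.set_aspect("equal")
    ax.set_axis_off()


def _savefig_deterministic(fig: matplotlib.figure.Figure, out_path: Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
        if out_path.suffix.lower() == ".svg":
            fig.savefig(out_path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out_path)


def render_chart(
    geom: ChartGeometry,
    out_path: str | Path,
    *,
    style: ChartStyle | None = None,
) -> Path:
    """Render one chart to SVG/PDF/PNG (by file suffix); returns the path."""
    style = style or ChartStyle()
    fig, ax = plt.subplots(figsize=(3, 3))
    try:
        _draw(ax, geom, style)
        _savefig_deterministic(fig, Path(out_path))
    finally:
        plt.close(fig)
    return Path(out_path)


def render_panel(
    records: Mapping[str, Mapping[str, PRSIndices]],
    out_path: str | Path,
    *,
    style: ChartStyle | None = None,
    radius_mode: str = "area",
) -> Path:
    """Render the species x scenario panel (rows = species, cols = scenarios).

    ``records`` maps species id -> {scenario -> PRSIndices}.  Species and
    scenario order are preserved as given; every species must provide the
    same scenario set.
    """
    if not records:
        raise ValueError("records table is empty")
    style = style or ChartStyle()
    species: Sequence[str] = list(records.keys())
    scenarios = list(records[species[0]].keys())
    for sp in species:
        if list(records[sp].keys()) != scenarios:
            raise ValueError(
                f"inconsistent scenario set for species {sp!r}: "
                f"{list(records[sp].keys())} != {scenarios}"
            )
    n_r, n_c = len(species), len(scenarios)
    fig, axes = plt.subplots(
        n_r, n_c, figsize=(1.8 * n_c + 0.8, 1.8 * n_r + 0.6), squeeze=False
    )
    try:
        for r, sp in enumerate(species):
            for c, sc in enumerate(scenarios):
                ax = axes[r][c]
                _draw(ax, chart_geometry(records[sp][sc], radius_mode=radius_mode), style)
                if r == 0:
                    ax.set_title(sc, fontsize=9)
            axes[r][0].set_axis_on()
            axes[r][0].set_xticks([])
            axes[r][0].set_yticks([])
            for side in axes[r][0].spines.values():
                side.set_visible(False)
            axes[r][0].set_ylabel(sp, fontsize=8)
        _savefig_deterministic(fig, Path(out_path))
    finally:
        plt.close(fig)
    return Path(out_path)
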