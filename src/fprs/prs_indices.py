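"""The five F-PRS range-shift indices: I, O, Dx, Dy, Dz.

Given a current-climate fuzzy range F_p, a future-climate fuzzy range F_f
(both suitability grids with memberships in [0, 1]) and a shared digital
elevation model, the index set quantifies:

* range increment  I  = (c(F_f) - c(F_p)) / c(F_p)    -- negative means
  contraction, positive expansion;
* range overlap    O  = c(min(F_p, F_f)) / c(max(F_p, F_f)), the fuzzy
  Jaccard ratio -- 0 means disjoint ranges, 1 complete congruence;
* centroid displacement (Dx, Dy, Dz) = membership-weighted range center
  of F_f minus that of F_p, in degrees longitude, degrees latitude and
  meters of elevation.

The overlap normalisation is a genuine convention choice: the prose
definition "proportion of overlap with the current range" admits both
c(∩)/c(F_p) and the Jaccard ratio.  Only the Jaccard form reaches 1
exactly when the two ranges are congruent, so it is the default; the
current-normalized variant remains available via ``overlap_convention``.
Every result record carries the convention that produced it.

Dx is a plain longitude difference in degrees — no cos-latitude
great-circle correction — and Cz for both periods is computed against the
same DEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_core import (
    DegenerateRangeError,
    ElevationGrid,
    SuitabilityGrid,
    assert_aligned,
    fuzzy_cardinality,
    fuzzy_intersection,
    fuzzy_union,
)

__all__ = [
    "Centroid3D",
    "PRSIndices",
    "range_increment",
    "range_overlap",
    "fuzzy_centroid",
    "range_displacement",
    "compute_prs",
    "OVERLAP_CONVENTIONS",
]

OVERLAP_CONVENTIONS = ("jaccard", "current_normalized")


@dataclass(frozen=True)
class Centroid3D:
    """Membership-weighted range center: (lon deg, lat deg, elevation m)."""

    cx: float
    cy: float
    cz: float


@dataclass(frozen=True)
class PRSIndices:
    """One species x scenario record of the five indices.

    ``card_current`` and ``card_future`` are the fuzzy cardinalities
    c(F_p) and c(F_f) the ratio indices were derived from;
    ``overlap_convention`` records how ``o_index`` was normalised.
    """

    i_index: float
    o_index: float
    dx: float
    dy: float
    dz: float
    card_current: float
    card_future: float
    overlap_convention: str = "jaccard"


def range_increment(fp: SuitabilityGrid, ff: SuitabilityGrid) -> float:
    """Relative change in fuzzy range area, (c(F_f) - c(F_p)) / c(F_p)."""
    assert_aligned(fp, ff)
    cp = fuzzy_cardinality(fp)
    if cp <= 0:
        raise DegenerateRangeError("current range has zero cardinality")
    return (fuzzy_cardinality(ff) - cp) / cp


def range_overlap(
    fp: SuitabilityGrid,
    ff: SuitabilityGrid,
    *,
    convention: str = "jaccard",
) -> float:
    """Fuzzy range overlap between the two periods.

    ``jaccard`` (default): c(∩)/c(∪); symmetric, 1 iff congruent.
    ``current_normalized``: c(∩)/c(F_p); asymmetric alternative reading.
    """
    if convention not in OVERLAP_CONVENTIONS:
        raise ValueError(f"unknown overlap convention {convention!r}")
    assert_aligned(fp, ff)
    c_int = fuzzy_cardinality(fuzzy_intersection(fp, ff))
    if convention == "jaccard":
        denom = fuzzy_cardinality(fuzzy_union(fp, ff))
        if denom <= 0:
            raise DegenerateRangeError("both ranges have zero cardinality")
    else:
        denom = fuzzy_cardinality(fp)
        if denom <= 0:
            raise DegenerateRangeError("current range has zero cardinality")
    return c_int / denom


def fuzzy_centroid(g: SuitabilityGrid, dem: ElevationGrid) -> Centroid3D:
    """Membership-weighted 3-D centroid of a fuzzy range.

    Cx = Σ μ_ij X_ij / Σ μ_ij and likewise for Cy (cell-center latitudes)
    and Cz (DEM elevations).  Cells with zero membership contribute
    nothing; masked cells are excluded.
    """
    assert_aligned(g, dem)
    w = np.where(g.mask, 0.0, g.values)
    total = w.sum()
    if total <= 0:
        raise DegenerateRangeError("range has zero cardinality; centroid undefined")
    x = g.spec.x_centers()  # (n_cols,)
    y = g.spec.y_centers()  # (n_rows,)
    cx = float((w.sum(axis=0) @ x) / total)
    cy = float((w.sum(axis=1) @ y) / total)
    cz = float((w * dem.values).sum() / total)
    return Centroid3D(cx, cy, cz)


def range_displacement(
    c_start: Centroid3D, c_end: Centroid3D
) -> tuple[float, float, float]:
    """(Dx, Dy, Dz): end-period centroid minus start-period centroid."""
    return (
        c_end.cx - c_start.cx,
        c_end.cy - c_start.cy,
        c_end.cz - c_start.cz,
    )


def compute_prs(
    fp: SuitabilityGrid,
    ff: SuitabilityGrid,
    dem: ElevationGrid,
    *,
    overlap_convention: str = "jaccard",
) -> PRSIndices:
    """Compute the full five-index record for one current/future pair.

    Each field equals the corresponding single-operation result exactly;
    this is a convenience composition, not a re-derivation.
    """
    assert_aligned(fp, ff)
    assert_aligned(fp, dem)
    cp = fuzzy_cardinality(fp)
    cf = fuzzy_cardinality(ff)
    if cp <= 0 or cf <= 0:
        raise DegenerateRangeError("both periods must have positive cardinality")
    i = range_increment(fp, ff)
    o = range_overlap(fp, ff, convention=overlap_convention)
    dx, dy, dz = range_displacement(
        fuzzy_centroid(fp, dem), fuzzy_centroid(ff, dem)
    )
    return PRSIndices(
        i_index=i,
        o_index=o,
        dx=dx,
        dy=dy,
        dz=dz,
        card_current=cp,
        card_future=cf,
        overlap_convention=overlap_convention,
    )
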