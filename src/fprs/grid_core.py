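"""Raster data model and fuzzy-set primitives.

A species' potential range under a continuous-output species distribution
model is treated as a fuzzy set over the grid: each cell belongs to the
range with a membership equal to the model's suitability output in [0, 1].
Everything downstream (range increment, overlap, centroid displacement) is
built from three primitives defined here: fuzzy cardinality (the sum of
memberships, the fuzzy analogue of range area in cells), and the Zadeh
intersection/union operators (cell-wise min/max).

Grids are plain numpy arrays plus a :class:`GridSpec`.  The convention,
fixed across the whole package, is: square cells in geographic degrees,
column index ``i`` increasing eastward, row index ``j`` increasing
northward (row 0 is the *southern* edge), and cell *centers* at
``(x_origin + (i + 0.5) * cell_size, y_origin + (j + 0.5) * cell_size)``.
NoData cells are masked and take part in no sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentError",
    "DegenerateRangeError",
    "GridSpec",
    "SuitabilityGrid",
    "ElevationGrid",
    "assert_aligned",
    "fuzzy_cardinality",
    "fuzzy_intersection",
    "fuzzy_union",
]


class AlignmentError(ValueError):
    """Two grids that must share a spec and mask do not."""


class DegenerateRangeError(ValueError):
    """An operation requiring positive fuzzy cardinality got an empty range."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid with square cells.

    Parameters
    ----------
    n_cols, n_rows
        Grid dimensions; at least 1 each.
    x_origin, y_origin
        Longitude of the west edge and latitude of the south edge, in
        degrees (cell *corner*, matching the ESRI ASCII ``xllcorner`` /
        ``yllcorner`` convention).
    cell_size
        Cell edge length in degrees; cells are square.
    nodata_sentinel
        Value used to mark NoData cells in file dialects.  In memory,
        NoData is carried by a boolean mask, not by this sentinel.
    """

    n_cols: int
    n_rows: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_sentinel: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("n_cols and n_rows must be >= 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east (length n_cols)."""
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Latitudes of cell centers, south to north (length n_rows)."""
        return self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> str | None:
        """Return the name of the first differing field, or None if equal.

        Origins and cell size are compared within ``tol`` degrees; the
        integer dimensions exactly.  The nodata sentinel is a file-dialect
        detail and is deliberately not compared.
        """
        if self.n_cols != other.n_cols:
            return "n_cols"
        if self.n_rows != other.n_rows:
            return "n_rows"
        if abs(self.x_origin - other.x_origin) > tol:
            return "x_origin"
        if abs(self.y_origin - other.y_origin) > tol:
            return "y_origin"
        if abs(self.cell_size - other.cell_size) > tol:
            return "cell_size"
        return None


def _as_grid_arrays(
    spec: GridSpec, values, mask, lo: float | None, hi: float | None, what: str
) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    if values.shape != spec.shape:
        raise ValueError(
            f"{what}: values shape {values.shape} != spec shape {spec.shape}"
        )
    if mask is None:
        mask = np.zeros(spec.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spec.shape:
            raise ValueError(f"{what}: mask shape {mask.shape} != spec shape")
    valid = values[~mask]
    if not np.all(np.isfinite(valid)):
        raise ValueError(f"{what}: non-finite value in an unmasked cell")
    if lo is not None and valid.size:
        if valid.min() < lo or valid.max() > hi:
            bad = np.argwhere(~mask & ((values < lo) | (values > hi)))[0]
            raise ValueError(
                f"{what}: value {values[tuple(bad)]!r} at (row={bad[0]}, "
                f"col={bad[1]}) outside [{lo}, {hi}]"
            )
    return values, mask


@dataclass
class SuitabilityGrid:
    """A fuzzy range set: memberships in [0, 1] on a georeferenced grid.

    ``values[j, i]`` is the membership of the cell in row ``j`` (from the
    south) and column ``i`` (from the west).  ``mask`` is True on NoData
    cells, which are excluded from every computation.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values, self.mask = _as_grid_arrays(
            self.spec, self.values, self.mask, 0.0, 1.0, "SuitabilityGrid"
        )


@dataclass
class ElevationGrid:
    """Cell elevations in meters a.s.l. on the same grid geometry."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values, self.mask = _as_grid_arrays(
            self.spec, self.values, self.mask, None, None, "ElevationGrid"
        )


Grid = SuitabilityGrid | ElevationGrid


def assert_aligned(a: Grid, b: Grid, *, tol: float = 1e-9) -> None:
    """Raise :class:`AlignmentError` unless the grids share spec and mask.

    The error message names the first differing field so callers can report
    actionable diagnostics (e.g. ``cell_size``).
    """
    diff = a.spec.approx_equal(b.spec, tol=tol)
    if diff is not None:
        raise AlignmentError(f"grids are not aligned: specs differ in {diff!r}")
    if not np.array_equal(a.mask, b.mask):
        raise AlignmentError("grids are not aligned: masks differ in 'mask'")


def fuzzy_cardinality(g: SuitabilityGrid, *, area_weighted: bool = False) -> float:
    """Sum of memberships over unmasked cells, c(F).

    This is the fuzzy-set cardinality: the fuzzy analogue of range area
    measured in cells.  By default the sum is unweighted (raw grid-cell
    semantics, matching legacy grid-based GIS workflows).  With
    ``area_weighted=True`` each cell is weighted by the cosine of its
    center latitude, an approximate correction for the east-west shrinkage
    of geographic cells toward the poles; this weighting is never used by
    the default index pipeline.

    Summation is compensated (math.fsum) so results on million-cell grids
    are stable to better than 1e-9 relative.
    """
    vals = g.values[~g.mask]
    if area_weighted:
        w = np.cos(np.deg2rad(g.spec.y_centers()))
        weights = np.broadcast_to(w[:, None], g.spec.shape)[~g.mask]
        vals = vals * weights
    return math.fsum(vals.tolist())


def _combine(a: SuitabilityGrid, b: SuitabilityGrid, op) -> SuitabilityGrid:
    # mask union: a cell missing in either input is missing in the result
    if a.spec.approx_equal(b.spec) is not None:
        raise AlignmentError(
            f"grids are not aligned: specs differ in {a.spec.approx_equal(b.spec)!r}"
        )
    mask = a.mask | b.mask
    values = op(a.values, b.values)
    values = np.where(mask, 0.0, values)
    return SuitabilityGrid(a.spec, values, mask)


def fuzzy_intersection(a: SuitabilityGrid, b: SuitabilityGrid) -> SuitabilityGrid:
    """Zadeh fuzzy intersection: cell-wise minimum of memberships."""
    return _combine(a, b, np.minimum)


def fuzzy_union(a: SuitabilityGrid, b: SuitabilityGrid) -> SuitabilityGrid:
    """Zadeh fuzzy union: cell-wise maximum of memberships."""
    return _combine(a, b, np.maximum)
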