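"""Virtual-species fixtures with analytic ground truth, plus aridity.

Real inputs to the index pipeline are MaxEnt-style logistic suitability
maps, a DEM and presence/absence evaluation tables — none of which can be
shipped.  This module generates stand-ins whose true index values are
known in closed form, so every downstream operation can be tested by
parameter recovery:

* suitability surfaces are bivariate Gaussians; in the continuum their
  fuzzy cardinality is ``peak * 2*pi*sigma_x*sigma_y / cell_area`` and
  their centroid is the Gaussian center, so translating the surface by
  (dx, dy) and scaling the sigmas by sqrt(e) yields exact expectations
  Dx = dx, Dy = dy and I = e - 1;
* DEMs are flat, linearly sloped northward, or a Gaussian ridge, giving
  closed-form Dz for sloped cases (Dz = slope * Dy on a north slope);
* evaluation samples draw presence/absence scores from shifted Beta
  distributions whose means differ exactly by ``separation``.

The generators are deterministic: identical parameters and seed give
bit-identical output.

The module also houses the growing-season aridity definition used in the
predictor protocol: the natural log of the ratio of total potential
evapotranspiration to total precipitation over months with mean
temperature strictly above 0 deg C.  PET is an input; no PET model is
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid_core import ElevationGrid, GridSpec, SuitabilityGrid

__all__ = [
    "VirtualSpeciesParams",
    "MonthlyClimate",
    "ShiftTruth",
    "make_dem",
    "make_virtual_suitability",
    "make_shift_pair",
    "make_eval_sample",
    "growing_season_aridity",
    "OffGridError",
]

#: Tolerated truncation loss of Gaussian mass at the grid boundary.
MAX_TRUNCATION_LOSS = 1e-3


class OffGridError(ValueError):
    """A generated surface leaks too much of its support past the grid edge."""


@dataclass(frozen=True)
class VirtualSpeciesParams:
    """A Gaussian virtual-species niche in geographic coordinates."""

    center: tuple[float, float]  # (lon deg, lat deg)
    spread: tuple[float, float]  # (sigma_x deg, sigma_y deg)
    peak: float = 1.0  # membership at the center, in (0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread[0] <= 0 or self.spread[1] <= 0:
            raise ValueError("spread must be positive")
        if not 0 < self.peak <= 1:
            raise ValueError("peak must be in (0, 1]")


@dataclass(frozen=True)
class MonthlyClimate:
    """Twelve monthly means/totals: temperature (degC), precip and PET (mm)."""

    temp: tuple[float, ...]
    precip: tuple[float, ...]
    pet: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("temp", "precip", "pet"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must have 12 monthly values")
        if min(self.precip) < 0 or min(self.pet) < 0:
            raise ValueError("precip and pet must be non-negative")


@dataclass(frozen=True)
class ShiftTruth:
    """Analytic expectations for a generated current/future pair."""

    i_index: float
    dx: float
    dy: float
    dz: float | None  # None when the DEM is not supplied/linear


def make_dem(spec: GridSpec, kind: str, **params) -> ElevationGrid:
    """Build a DEM of one of three analytic shapes.

    ``flat``: constant ``elevation`` (default 0 m).
    ``north_slope``: ``base + slope * (lat - lat0)`` with ``slope`` in
    meters per degree latitude; ``lat0`` defaults to the south edge.
    ``ridge``: Gaussian ridge ``base + height * exp(-(d/width)**2 / 2)``
    where ``d`` is distance in degrees from the ridge ``axis`` (a
    longitude when ``orient="ns"``, a latitude when ``orient="ew"``).
    """
    x = spec.x_centers()
    y = spec.y_centers()
    if kind == "flat":
        z = np.full(spec.shape, float(params.get("elevation", 0.0)))
    elif kind == "north_slope":
        base = float(params.get("base", 0.0))
        slope = float(params.get("slope", 100.0))
        lat0 = float(params.get("lat0", spec.y_origin))
        z = np.broadcast_to(
            (base + slope * (y - lat0))[:, None], spec.shape
        ).copy()
    elif kind == "ridge":
        base = float(params.get("base", 0.0))
        height = float(params.get("height", 1000.0))
        width = float(params.get("width", 1.0))
        axis = float(params.get("axis", 0.0))
        orient = params.get("orient", "ns")
        if orient == "ns":
            d = x - axis
            z = np.broadcast_to(
                (base + height * np.exp(-0.5 * (d / width) ** 2))[None, :],
                spec.shape,
            ).copy()
        elif orient == "ew":
            d = y - axis
            z = np.broadcast_to(
                (base + height * np.exp(-0.5 * (d / width) ** 2))[:, None],
                spec.shape,
            ).copy()
        else:
            raise ValueError(f"unknown ridge orient {orient!r}")
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")
    return ElevationGrid(spec, z)


def make_virtual_suitability(
    spec: GridSpec, p: VirtualSpeciesParams
) -> SuitabilityGrid:
    """Gaussian suitability surface evaluated at cell centers."""
    x = spec.x_centers()
    y = spec.y_centers()
    cx, cy = p.center
    sx, sy = p.spread
    gx = np.exp(-0.5 * ((x - cx) / sx) ** 2)
    gy = np.exp(-0.5 * ((y - cy) / sy) ** 2)
    values = p.peak * gy[:, None] * gx[None, :]
    return SuitabilityGrid(spec, values)


def _analytic_cardinality(spec: GridSpec, p: VirtualSpeciesParams) -> float:
    """Continuum fuzzy cardinality of an untruncated Gaussian surface."""
    sx, sy = p.spread
    return p.peak * 2.0 * math.pi * sx * sy / spec.cell_size**2


def _check_on_grid(
    spec: GridSpec, p: VirtualSpeciesParams, grid: SuitabilityGrid
) -> None:
    from .grid_core import fuzzy_cardinality

    analytic = _analytic_cardinality(spec, p)
    actual = fuzzy_cardinality(grid)
    loss = 1.0 - actual / analytic
    if loss > MAX_TRUNCATION_LOSS:
        raise OffGridError(
            f"surface at {p.center} loses {loss:.2%} of its mass past the "
            f"grid boundary (allowed {MAX_TRUNCATION_LOSS:.2%})"
        )


def make_shift_pair(
    spec: GridSpec,
    base: VirtualSpeciesParams,
    dx: float,
    dy: float,
    expansion: float = 1.0,
) -> tuple[SuitabilityGrid, SuitabilityGrid, ShiftTruth]:
    """Current/future surface pair with known index expectations.

    The future surface is the base Gaussian translated by (dx, dy)
    degrees with both sigmas scaled by sqrt(expansion) and the peak kept,
    so in the continuum c(F_f)/c(F_p) = expansion exactly.  Truth:
    I = expansion - 1, Dx = dx, Dy = dy (Dz depends on the DEM and is
    left None; on a linear north slope it is slope * dy).

    Raises :class:`OffGridError` when either surface loses more than
    0.1% of its Gaussian mass past the grid boundary.
    """
    if expansion <= 0:
        raise ValueError("expansion must be positive")
    fp = make_virtual_suitability(spec, base)
    _check_on_grid(spec, base, fp)
    s = math.sqrt(expansion)
    fut = VirtualSpeciesParams(
        center=(base.center[0] + dx, base.center[1] + dy),
        spread=(base.spread[0] * s, base.spread[1] * s),
        peak=base.peak,
        seed=base.seed,
    )
    ff = make_virtual_suitability(spec, fut)
    _check_on_grid(spec, fut, ff)
    truth = ShiftTruth(i_index=expansion - 1.0, dx=dx, dy=dy, dz=None)
    return fp, ff, truth


def make_eval_sample(
    n_pres: int, n_abs: int, separation: float, seed: int
):
    """Presence/absence scores from Beta distributions split by ``separation``.

    Absence scores are ``(1 - separation) * Beta(3, 3)`` (support
    [0, 1 - separation], mean (1 - separation)/2); presence scores are
    ``separation + (1 - separation) * Beta(3, 3)``.  The class means
    differ by exactly ``separation``; supports are disjoint once
    separation exceeds 0.5, giving AUC = 1.  ``separation = 0`` makes the
    classes exchangeable (AUC -> 0.5).  Deterministic per seed.
    """
    from .model_eval import EvalSample

    if n_pres < 1 or n_abs < 1:
        raise ValueError("need at least one presence and one absence")
    if not 0 <= separation <= 1:
        raise ValueError("separation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = 1.0 - separation
    abs_scores = width * rng.beta(3, 3, size=n_abs)
    pres_scores = separation + width * rng.beta(3, 3, size=n_pres)
    labels = np.concatenate(
        [np.ones(n_pres, dtype=bool), np.zeros(n_abs, dtype=bool)]
    )
    scores = np.concatenate([pres_scores, abs_scores])
    return EvalSample(labels=labels, scores=scores)


def growing_season_aridity(clim: MonthlyClimate) -> float:
    """ln(total PET / total precipitation) over months with T > 0 degC.

    The growing season is defined by monthly mean temperature strictly
    above 0 deg C; months at or below freezing contribute nothing.
    """
    months = [m for m in range(12) if clim.temp[m] > 0.0]
    if not months:
        raise ValueError("no growing season: no month has temperature > 0 degC")
    total_precip = sum(clim.precip[m] for m in months)
    total_pet = sum(clim.pet[m] for m in months)
    if total_precip <= 0:
        raise ValueError("growing-season precipitation is zero; aridity undefined")
    return math.log(total_pet / total_precip)
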