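"""Quadratic trend surface in home coordinates plus distance to the CBD.

Smooth spatial variation in travel behaviour is captured by six covariates
derived from the home location: the (standardized) planar coordinates, their
product and squares, and the straight-line distance to the central business
district in kilometres.  Both behavioural models include this block, and grid
prediction re-evaluates it at each cell centroid.

Coordinates are z-scored before the polynomial expansion (raw projected
metres squared would put design-matrix columns many orders of magnitude
apart and wreck the optimizer's conditioning); the fitted
:class:`CoordinateScaler` is serialized with each model so that predictions
use the estimation-sample scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateScaleError

#: Encoded names of the six trend covariates, in design order.
TREND_NAMES = (
    "trend:x",
    "trend:y",
    "trend:xy",
    "trend:x2",
    "trend:y2",
    "trend:cbd_km",
)


@dataclass(frozen=True)
class CoordinateScaler:
    """Per-axis centering and scaling of planar coordinates."""

    center_xy: tuple[float, float]
    scale_xy: tuple[float, float]

    def __post_init__(self):
        if not (self.scale_xy[0] > 0 and self.scale_xy[1] > 0):
            raise DegenerateScaleError("coordinate scales must be positive")

    def transform(self, xy: np.ndarray) -> np.ndarray:
        """Scale an (n, 2) array (or a single pair) of coordinates."""
        xy = np.asarray(xy, dtype=float)
        return (xy - np.asarray(self.center_xy)) / np.asarray(self.scale_xy)

    def to_dict(self) -> dict:
        return {"center_xy": list(self.center_xy), "scale_xy": list(self.scale_xy)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoordinateScaler":
        return cls(tuple(d["center_xy"]), tuple(d["scale_xy"]))


@dataclass(frozen=True)
class TrendTerms:
    """The six trend-surface covariate values at one location."""

    x: float
    y: float
    xy: float
    x2: float
    y2: float
    cbd_km: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.xy, self.x2, self.y2, self.cbd_km])


def fit_scaler(points: Sequence) -> CoordinateScaler:
    """Fit a :class:`CoordinateScaler` (mean / population SD per axis).

    Raises :class:`~cpmap.errors.DegenerateScaleError` when an axis has zero
    variance (e.g. a single point, or all points collinear along an axis).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateScaleError("need at least two coordinate pairs")
    center = pts.mean(axis=0)
    scale = pts.std(axis=0)  # population SD: scaled sample has mean 0, sd 1
    if np.any(scale <= 0):
        raise DegenerateScaleError("zero coordinate variance on at least one axis")
    return CoordinateScaler(tuple(center), tuple(scale))


def cbd_distance_km(xy, cbd_xy) -> np.ndarray | float:
    """Euclidean distance to the CBD in kilometres (planar map units)."""
    xy = np.asarray(xy, dtype=float)
    d = np.linalg.norm(xy - np.asarray(cbd_xy, dtype=float), axis=-1)
    return d / 1000.0


def trend_terms(xy, scaler: CoordinateScaler, cbd_xy) -> TrendTerms:
    """Trend covariates for one location.

    The coordinates are standardized by ``scaler`` before the quadratic
    expansion; the CBD term is the raw Euclidean distance in km.
    """
    sx, sy = scaler.transform(np.asarray(xy, dtype=float))
    return TrendTerms(
        x=float(sx),
        y=float(sy),
        xy=float(sx * sy),
        x2=float(sx * sx),
        y2=float(sy * sy),
        cbd_km=float(cbd_distance_km(xy, cbd_xy)),
    )


def trend_matrix(xy: np.ndarray, scaler: CoordinateScaler, cbd_km: np.ndarray) -> np.ndarray:
    """Vectorized trend block: (n, 6) matrix from (n, 2) coordinates and a
    precomputed (n,) CBD-distance vector (km).

    Accepting the CBD distances separately lets diary records carry survey-
    supplied (possibly network-based) distances while grid prediction uses
    straight-line distances from the grid's CBD point.
    """
    s = scaler.transform(np.asarray(xy, dtype=float).reshape(-1, 2))
    x, y = s[:, 0], s[:, 1]
    return np.column_stack([x, y, x * y, x * x, y * y, np.asarray(cbd_km, dtype=float)])
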