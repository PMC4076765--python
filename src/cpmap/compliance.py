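"""Compliance Potential Mapping: map algebra over the two fitted models.

For a fixed person profile, each grid cell centroid yields a predicted
walking trip distance ``d_hat`` (metres) and the probabilities of making
1, 2 or 3+ walking trips.  These combine into:

* total daily walking distance (metres/day)::

      TDWD = d_hat * (1 * P(1) + 2 * P(2) + k_cap * P(3+))

  where the open class 3+ is valued at ``k_cap`` trips (default 3, a
  conservative lower bound);
* weekly walking minutes, assuming the daily behaviour repeats ``w`` days a
  week at walking speed ``s``::

      WWM = TDWD * w / s

* compliance percent, ``100 * WWM / guideline minutes``, deliberately not
  capped at 100.

Defaults follow the seniors' guideline arithmetic: 150 min/week, a walking
speed of 68.4 m/min (so the guideline equals 10.26 km of walking per week)
and w = 5 days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CovariateSchema, GridSpec
from .errors import ConfigurationError, ParameterDomainError
from .joint_distance_model import JointModelParams, predict_distance
from .ordered_frequency_model import OrderedProbitParams, marginal_class_probs
from .trend_surface import TrendTerms, cbd_distance_km, trend_terms

#: Raster layer names in output order.
LAYER_NAMES = ("d_hat", "p1", "p2", "p3plus", "tdwd", "wwm", "compliance")


@dataclass(frozen=True)
class Profile:
    """A fixed person archetype whose covariates are evaluated everywhere."""

    covariates: Mapping[str, object]
    name: str = "profile"

    def to_dict(self) -> dict:
        return {"name": self.name, "covariates": dict(self.covariates)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Profile":
        return cls(covariates=dict(d["covariates"]), name=d.get("name", "profile"))

    @classmethod
    def load(cls, path) -> "Profile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class GuidelineConfig:
    """Physical-activity guideline arithmetic.

    ``weekly_minutes``: recommended minimum activity (min/week);
    ``walking_speed``: assumed constant speed (m/min);
    ``days_per_week``: how many days the diary day is assumed to repeat.
    """

    weekly_minutes: float = 150.0
    walking_speed: float = 68.4
    days_per_week: int = 5

    def __post_init__(self):
        if not (self.weekly_minutes > 0 and self.walking_speed > 0 and self.days_per_week > 0):
            raise ParameterDomainError("guideline quantities must be strictly positive")


def tdwd(d_hat: float, probs: np.ndarray, k_cap: int = 3) -> float:
    """Expected total daily walking distance (metres/day).

    ``probs`` is the class-probability vector over {0, 1, 2, 3+}; class 0
    contributes nothing and 3+ is valued at ``k_cap`` trips.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (4,) or np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-8:
        raise ParameterDomainError("probs must be 4 nonnegative values summing to 1")
    if not d_hat > 0:
        raise ParameterDomainError("d_hat must be positive")
    k = np.array([0.0, 1.0, 2.0, float(k_cap)])
    return float(d_hat * (k @ probs))


def wwm(tdwd_m: float, cfg: GuidelineConfig = GuidelineConfig()) -> float:
    """Weekly walking minutes from a daily walking distance in metres."""
    return tdwd_m * cfg.days_per_week / cfg.walking_speed


def compliance_percent(wwm_min: float, cfg: GuidelineConfig = GuidelineConfig()) -> float:
    """Percent of the weekly guideline met by walking (not capped at 100)."""
    return 100.0 * wwm_min / cfg.weekly_minutes


def guideline_distance_km(cfg: GuidelineConfig = GuidelineConfig()) -> float:
    """Walking distance per week equivalent to the guideline minutes (km)."""
    return cfg.weekly_minutes * cfg.walking_speed / 1000.0


@dataclass
class ComplianceRaster:
    """Per-cell layers of the compliance computation on a regular grid."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    profile: Profile | None = None

    def __post_init__(self):
        for name in LAYER_NAMES:
            if name not in self.layers:
                raise ConfigurationError(f"missing raster layer {name!r}")
            if self.layers[name].shape != self.grid.shape:
                raise ConfigurationError(f"layer {name!r} shape != grid shape")

    def to_dataframe(self) -> pd.DataFrame:
        cent = self.grid.centroids().reshape(-1, 2)
        cols = {"cell_x": cent[:, 0], "cell_y": cent[:, 1]}
        for name in LAYER_NAMES:
            key = "compliance_pct" if name == "compliance" else name
            cols[key] = self.layers[name].ravel()
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_ascii_grids(self, prefix) -> list[str]:
        """One ESRI ASCII grid (.asc) per layer; returns the paths written."""
        paths = []
        for name in LAYER_NAMES:
            path = f"{prefix}_{name}.asc"
            _write_esri_ascii(path, self.grid, self.layers[name])
            paths.append(path)
        return paths


def _write_esri_ascii(path, grid: GridSpec, values: np.ndarray) -> None:
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_xy[0]}\n"
        f"yllcorner {grid.origin_xy[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.6g")  # .asc rows run north to south


def build_compliance_raster(
    profile: Profile,
    dist_model: JointModelParams,
    freq_model: OrderedProbitParams,
    grid: GridSpec,
    cfg: GuidelineConfig = GuidelineConfig(),
    k_cap: int = 3,
) -> ComplianceRaster:
    """Evaluate the compliance chain at every cell centroid.

    Each model standardizes the centroid coordinates with its own serialized
    scaler; the CBD distance is straight-line from ``grid.cbd_xy``.  The
    computation is deterministic for fixed inputs.
    """
    if dist_model.schema.to_dict() != freq_model.schema.to_dict():
        raise ConfigurationError("distance and frequency models use different schemas")
    try:
        design = dist_model.schema.encode(profile.covariates)
    except KeyError as exc:
        raise ConfigurationError(f"profile is missing covariate {exc}") from exc

    cent = grid.centroids().reshape(-1, 2)
    d_hat = np.empty(grid.n_cells)
    probs = np.empty((grid.n_cells, 4))
    for i, xy in enumerate(cent):
        t_dist = trend_terms(xy, dist_model.scaler, grid.cbd_xy)
        t_freq = trend_terms(xy, freq_model.scaler, grid.cbd_xy)
        d_hat[i] = predict_distance(design, t_dist, dist_model, "walk")
        probs[i] = marginal_class_probs(design, t_freq, freq_model, "walk")

    k = np.array([0.0, 1.0, 2.0, float(k_cap)])
    tdwd_v = d_hat * (probs @ k)
    wwm_v = tdwd_v * cfg.days_per_week / cfg.walking_speed
    comp_v = 100.0 * wwm_v / cfg.weekly_minutes

    shape = grid.shape
    layers = {
        "d_hat": d_hat.reshape(shape),
        "p1": probs[:, 1].reshape(shape),
        "p2": probs[:, 2].reshape(shape),
        "p3plus": probs[:, 3].reshape(shape),
        "tdwd": tdwd_v.reshape(shape),
        "wwm": wwm_v.reshape(shape),
        "compliance": comp_v.reshape(shape),
    }
    return ComplianceRaster(grid=grid, layers=layers, profile=profile)


@dataclass(frozen=True)
class AreaHistogram:
    """Area (km^2) per compliance bin, plus the out-of-range area.

    ``area_km2[i]`` covers ``bin_edges[i] <= value < bin_edges[i+1]`` (the
    last bin is closed on the right).  ``underflow``/``overflow`` hold the
    area outside the edges, so ``area_km2.sum() + underflow + overflow``
    always equals the grid area.
    """

    bin_edges: np.ndarray
    area_km2: np.ndarray
    underflow: float
    overflow: float

    @property
    def total_km2(self) -> float:
        return float(self.area_km2.sum() + self.underflow + self.overflow)


def area_by_compliance(
    raster: ComplianceRaster,
    bin_edges: Sequence[float],
    layer: str = "compliance",
    mask: np.ndarray | None = None,
) -> AreaHistogram:
    """Distribution of grid area by compliance value.

    ``mask`` (optional, boolean, grid-shaped) restricts the tally, e.g. to
    exclude water or non-residential cells.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterDomainError("bin_edges must be strictly increasing, length >= 2")
    values = raster.layers[layer]
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    v = values.ravel()
    cell = raster.grid.cell_area_km2
    counts, _ = np.histogram(v, bins=edges)
    under = int(np.sum(v < edges[0]))
    over = int(np.sum(v > edges[-1]))
    return AreaHistogram(
        bin_edges=edges,
        area_km2=counts * cell,
        underflow=under * cell,
        overflow=over * cell,
    )


def plot_compliance(raster: ComplianceRaster, layer: str = "compliance", ax=None):
    """Minimal choropleth of one raster layer (matplotlib imshow)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g = raster.grid
    x0, y0 = g.origin_xy
    im = ax.imshow(
        raster.layers[layer],
        origin="lower",
        extent=(x0, x0 + g.n_cols * g.cell_size, y0, y0 + g.n_rows * g.cell_size),
    )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(layer)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
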