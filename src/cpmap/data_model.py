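"""Domain types and delimited-text I/O for travel-diary tables.

The package consumes two flat tables derived from a household travel survey:

* a *trip* table — one row per observed trip (person, mode, distance,
  home coordinates, distance to the central business district, covariates);
* a *person* table — one row per surveyed person with per-mode trip counts
  and the same covariates.

Covariates are described by a :class:`CovariateSchema`: an ordered list of
categorical variables (with an explicit reference level, encoded as k-1
dummies) and continuous variables (passed through).  The one supported
dialect is comma-separated text with a mandatory header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EncodingError, RowError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical mode order used throughout the package.
MODES: tuple[str, str, str] = ("walk", "car", "transit")

#: Fixed non-covariate columns of the trip table, in file order.
TRIP_BASE_COLUMNS = ("person_id", "mode", "distance_m", "x", "y", "cbd_km")

#: Fixed non-covariate columns of the person table, in file order.
PERSON_BASE_COLUMNS = ("person_id", "n_walk", "n_car", "n_transit", "x", "y", "cbd_km")


@dataclass(frozen=True)
class Categorical:
    """A categorical covariate with an explicit reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"duplicate levels in categorical {self.name!r}")
        if self.reference not in self.levels:
            raise SchemaError(
                f"reference {self.reference!r} is not a level of {self.name!r}"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class Continuous:
    """A continuous covariate, passed through unchanged."""

    name: str


Variable = Union[Categorical, Continuous]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate description shared by readers, models and profiles.

    Categorical variables are expanded to reference-cell dummies (one
    indicator per non-reference level); continuous variables map to a single
    column.  The expansion order is deterministic: variables in declaration
    order, levels in declaration order.
    """

    variables: tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("covariate names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def encoded_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for v in self.variables:
            if isinstance(v, Categorical):
                out.extend(f"{v.name}[{l}]" for l in v.nonreference_levels)
            else:
                out.append(v.name)
        return tuple(out)

    @property
    def n_encoded(self) -> int:
        return len(self.encoded_names)

    def encode(self, covariates: Mapping[str, object]) -> np.ndarray:
        """Encode one raw covariate mapping into a design vector."""
        out = np.zeros(self.n_encoded)
        j = 0
        for v in self.variables:
            if isinstance(v, Categorical):
                value = str(covariates[v.name])
                if value not in v.levels:
                    raise EncodingError(
                        f"{value!r} is not a level of {v.name!r} "
                        f"(levels: {', '.join(v.levels)})"
                    )
                for l in v.nonreference_levels:
                    out[j] = 1.0 if value == l else 0.0
                    j += 1
            else:
                out[j] = float(covariates[v.name])
                j += 1
        return out

    def to_dict(self) -> dict:
        vs = []
        for v in self.variables:
            if isinstance(v, Categorical):
                vs.append(
                    {
                        "kind": "categorical",
                        "name": v.name,
                        "levels": list(v.levels),
                        "reference": v.reference,
                    }
                )
            else:
                vs.append({"kind": "continuous", "name": v.name})
        return {"variables": vs}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        vs: list[Variable] = []
        for v in d["variables"]:
            if v["kind"] == "categorical":
                vs.append(Categorical(v["name"], tuple(v["levels"]), v["reference"]))
            elif v["kind"] == "continuous":
                vs.append(Continuous(v["name"]))
            else:
                raise SchemaError(f"unknown variable kind {v['kind']!r}")
        return cls(tuple(vs))


@dataclass(frozen=True)
class TripRecord:
    """One observed trip.

    ``distance_m`` must be strictly positive: zero-distance diary rows carry
    no information about trip length and are excluded at read time.
    """

    person_id: str
    mode: str
    distance_m: float
    covariates: Mapping[str, object]
    home_xy: tuple[float, float]
    cbd_distance_km: float

    def __post_init__(self):
        if self.mode not in MODES:
            raise SchemaError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not self.distance_m > 0:
            raise SchemaError("trip distance must be strictly positive")
        if self.cbd_distance_km < 0:
            raise SchemaError("CBD distance must be nonnegative")


@dataclass(frozen=True)
class PersonRecord:
    """One surveyed person with per-mode trip counts."""

    person_id: str
    counts: Mapping[str, int]
    covariates: Mapping[str, object]
    home_xy: tuple[float, float]
    cbd_distance_km: float

    def __post_init__(self):
        for m in MODES:
            if int(self.counts.get(m, 0)) < 0:
                raise SchemaError(f"negative trip count for mode {m!r}")
        if self.cbd_distance_km < 0:
            raise SchemaError("CBD distance must be nonnegative")


@dataclass(frozen=True)
class GridSpec:
    """A regular prediction grid.

    ``origin_xy`` is the lower-left corner in planar map units (metres);
    cells are squares of side ``cell_size`` (default 250 m).  Row index
    increases northward.  ``cbd_xy`` locates the central business district
    used for the trend-surface distance term.
    """

    origin_xy: tuple[float, float]
    n_rows: int
    n_cols: int
    cbd_xy: tuple[float, float]
    cell_size: float = 250.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise SchemaError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise SchemaError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def centroids(self) -> np.ndarray:
        """Cell-centroid coordinates, shape (n_rows, n_cols, 2)."""
        x0, y0 = self.origin_xy
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.stack([xx, yy], axis=-1)

    def to_dict(self) -> dict:
        return {
            "origin_xy": list(self.origin_xy),
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cbd_xy": list(self.cbd_xy),
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            origin_xy=tuple(d["origin_xy"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cbd_xy=tuple(d["cbd_xy"]),
            cell_size=float(d.get("cell_size", 250.0)),
        )


class TripList(list):
    """List of :class:`TripRecord` with the count of dropped zero-distance rows."""

    n_dropped: int = 0


def _check_columns(df: pd.DataFrame, base: Sequence[str], schema: CovariateSchema, path):
    missing = [c for c in (*base, *schema.names) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _covariate_mapping(row: Mapping, schema: CovariateSchema, line: int) -> dict:
    cov: dict[str, object] = {}
    for v in schema.variables:
        raw = row[v.name]
        if isinstance(v, Continuous):
            try:
                cov[v.name] = float(raw)
            except (TypeError, ValueError):
                raise RowError(f"column {v.name!r}: not a number: {raw!r}", line)
        else:
            cov[v.name] = str(raw)
    return cov


def _float_field(row: Mapping, name: str, line: int) -> float:
    try:
        return float(row[name])
    except (TypeError, ValueError):
        raise RowError(f"column {name!r}: not a number: {row[name]!r}", line)


def read_trips(path, schema: CovariateSchema) -> TripList:
    """Read a trip CSV, dropping (and counting) rows with distance <= 0.

    Returns a list of :class:`TripRecord` whose ``n_dropped`` attribute holds
    the number of excluded zero/negative-distance rows.
    """
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, TRIP_BASE_COLUMNS, schema, path)
    trips = TripList()
    dropped = 0
    for idx, row in enumerate(df.to_dict("records")):
        line = idx + 2  # header is line 1
        d = _float_field(row, "distance_m", line)
        if not d > 0:
            dropped += 1
            continue
        mode = str(row["mode"])
        if mode not in MODES:
            raise RowError(f"unknown mode {mode!r}", line)
        trips.append(
            TripRecord(
                person_id=str(row["person_id"]),
                mode=mode,
                distance_m=d,
                covariates=_covariate_mapping(row, schema, line),
                home_xy=(_float_field(row, "x", line), _float_field(row, "y", line)),
                cbd_distance_km=_float_field(row, "cbd_km", line),
            )
        )
    trips.n_dropped = dropped
    if dropped:
        logger.info("read_trips: dropped %d row(s) with distance <= 0", dropped)
    return trips


def write_trips(trips: Iterable[TripRecord], path, schema: CovariateSchema) -> None:
    rows = []
    for t in trips:
        row = {
            "person_id": t.person_id,
            "mode": t.mode,
            "distance_m": t.distance_m,
            "x": t.home_xy[0],
            "y": t.home_xy[1],
            "cbd_km": t.cbd_distance_km,
        }
        row.update({n: t.covariates[n] for n in schema.names})
        rows.append(row)
    pd.DataFrame(rows, columns=[*TRIP_BASE_COLUMNS, *schema.names]).to_csv(
        path, index=False
    )


def read_persons(path, schema: CovariateSchema) -> list[PersonRecord]:
    """Read a person CSV with per-mode trip counts."""
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, PERSON_BASE_COLUMNS, schema, path)
    persons: list[PersonRecord] = []
    for idx, row in enumerate(df.to_dict("records")):
        line = idx + 2
        counts = {}
        for m in MODES:
            raw = row[f"n_{m}"]
            try:
                counts[m] = int(raw)
            except (TypeError, ValueError):
                raise RowError(f"column n_{m!r}: not an integer: {raw!r}", line)
            if counts[m] < 0:
                raise RowError(f"column n_{m}: negative count", line)
        persons.append(
            PersonRecord(
                person_id=str(row["person_id"]),
                counts=counts,
                covariates=_covariate_mapping(row, schema, line),
                home_xy=(_float_field(row, "x", line), _float_field(row, "y", line)),
                cbd_distance_km=_float_field(row, "cbd_km", line),
            )
        )
    return persons


def write_persons(persons: Iterable[PersonRecord], path, schema: CovariateSchema) -> None:
    rows = []
    for p in persons:
        row = {
            "person_id": p.person_id,
            "n_walk": int(p.counts.get("walk", 0)),
            "n_car": int(p.counts.get("car", 0)),
            "n_transit": int(p.counts.get("transit", 0)),
            "x": p.home_xy[0],
            "y": p.home_xy[1],
            "cbd_km": p.cbd_distance_km,
        }
        row.update({n: p.covariates[n] for n in schema.names})
        rows.append(row)
    pd.DataFrame(rows, columns=[*PERSON_BASE_COLUMNS, *schema.names]).to_csv(
        path, index=False
    )


def encode_covariates(record, schema: CovariateSchema) -> np.ndarray:
    """Design vector (reference-cell dummies + continuous pass-through) for a
    trip or person record."""
    return schema.encode(record.covariates)
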