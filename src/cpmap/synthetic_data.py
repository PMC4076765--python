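"""Synthetic travel-diary generator with known ground truth.

Generates a survey with exactly the statistical structure the two models
assume, so estimator output can be compared against true parameters:

* persons live uniformly in a rectangular city; built-environment intensity
  declines smoothly with distance from the CBD;
* per-mode trip-frequency classes come from the trivariate ordered probit
  read generatively: latent ``t*_j = beta_j' x + eps_j`` with eps drawn from
  MVN(0, R), thresholded into {0, 1, 2, 3+} (the open class is realized as
  exactly three trips);
* each person's trips (their realized total count) get a mode drawn from
  the MNL probabilities and a log-normal distance whose normal score is
  correlated (coefficient rho) with the truncated selection score of the
  chosen mode — the Gaussian-copula construction whose implied density is
  exactly the joint model's likelihood, which is what makes parameter
  recovery a valid test.

Default parameters emulate the broad features of a large Canadian
metropolitan seniors' travel survey: mode shares near 17/63/19 percent for
walk/car/transit, mean walking trip distance around 0.74 km, log-distance
scale 1.084 and selection correlation -0.472, and latent frequency
correlations (-0.474, -0.231, -0.656) for (walk,car), (walk,transit),
(car,transit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtri

from ._design import covariate_matrix
from .data_model import (
    MODES,
    Categorical,
    Continuous,
    CovariateSchema,
    GridSpec,
    PersonRecord,
    TripRecord,
)
from .errors import ConfigurationError, ParameterDomainError
from .joint_distance_model import JointModelParams, _coef_matrices
from .ordered_frequency_model import OrderedProbitParams, _params_matrices
from .trend_surface import TREND_NAMES, CoordinateScaler, cbd_distance_km


@dataclass(frozen=True)
class CategoricalGenerator:
    """Level frequencies for one categorical covariate (aligned with the
    schema's level order)."""

    probs: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
            raise ConfigurationError("categorical frequencies must be >= 0 and sum to 1")


@dataclass(frozen=True)
class ContinuousGenerator:
    """Gaussian covariate with a linear CBD-distance gradient:
    value = mean + cbd_slope * cbd_km + N(0, sd)."""

    mean: float
    sd: float
    cbd_slope: float = 0.0


@dataclass
class SimulationConfig:
    n_persons: int
    seed: int
    true_joint: JointModelParams
    true_freq: OrderedProbitParams
    city: GridSpec
    covariate_generators: dict[str, object]

    def __post_init__(self):
        if self.true_joint.schema.to_dict() != self.true_freq.schema.to_dict():
            raise ConfigurationError("the two true models must share one schema")
        for v in self.true_joint.schema.variables:
            gen = self.covariate_generators.get(v.name)
            if isinstance(v, Categorical):
                if not isinstance(gen, CategoricalGenerator) or len(gen.probs) != len(v.levels):
                    raise ConfigurationError(f"bad generator for categorical {v.name!r}")
            elif not isinstance(gen, ContinuousGenerator):
                raise ConfigurationError(f"bad generator for continuous {v.name!r}")

    @property
    def schema(self) -> CovariateSchema:
        return self.true_joint.schema


def _rngs(cfg: SimulationConfig) -> tuple[np.random.Generator, np.random.Generator]:
    """Two independent deterministic streams from the one config seed."""
    ss = np.random.SeedSequence(cfg.seed)
    c1, c2 = ss.spawn(2)
    return np.random.default_rng(c1), np.random.default_rng(c2)


def simulate_persons(cfg: SimulationConfig) -> list[PersonRecord]:
    """Draw persons, locations, covariates and frequency classes."""
    rng, _ = _rngs(cfg)
    n = cfg.n_persons
    x0, y0 = cfg.city.origin_xy
    W = cfg.city.n_cols * cfg.city.cell_size
    H = cfg.city.n_rows * cfg.city.cell_size
    xy = np.column_stack([x0 + W * rng.random(n), y0 + H * rng.random(n)])
    cbd = cbd_distance_km(xy, cfg.city.cbd_xy)

    covs: list[dict[str, object]] = [dict() for _ in range(n)]
    for v in cfg.schema.variables:
        gen = cfg.covariate_generators[v.name]
        if isinstance(v, Categorical):
            draws = rng.choice(len(v.levels), size=n, p=gen.probs)
            for i in range(n):
                covs[i][v.name] = v.levels[draws[i]]
        else:
            vals = gen.mean + gen.cbd_slope * cbd + gen.sd * rng.standard_normal(n)
            for i in range(n):
                covs[i][v.name] = float(vals[i])

    # latent propensities and classes
    records = [
        PersonRecord(
            person_id=f"p{i:06d}",
            counts={m: 0 for m in MODES},
            covariates=covs[i],
            home_xy=(float(xy[i, 0]), float(xy[i, 1])),
            cbd_distance_km=float(cbd[i]),
        )
        for i in range(n)
    ]
    X = covariate_matrix(records, cfg.schema, cfg.true_freq.scaler)
    coefs, thr, R = _params_matrices(cfg.true_freq)
    eta = X @ coefs  # (n, 3)
    L = np.linalg.cholesky(R)
    eps = rng.standard_normal((n, 3)) @ L.T
    latent = eta + eps
    classes = np.sum(latent[:, :, None] > thr[None, :, :], axis=2)  # (n,3) in 0..3

    out = []
    for i, r in enumerate(records):
        counts = {m: int(classes[i, j]) for j, m in enumerate(MODES)}
        out.append(
            PersonRecord(
                person_id=r.person_id,
                counts=counts,
                covariates=r.covariates,
                home_xy=r.home_xy,
                cbd_distance_km=r.cbd_distance_km,
            )
        )
    return out


def simulate_trips(
    persons: Sequence[PersonRecord], cfg: SimulationConfig
) -> list[TripRecord]:
    """Draw trips for the realized per-person totals (class 3+ = 3 trips).

    Modes come from the MNL; the chosen mode's selection score is a
    truncated standard normal ``e | e <= ndtri(P_m)``, and the log-distance
    score is ``rho e + sqrt(1 - rho^2) z`` — so (mode, distance) follow
    exactly the joint model's density.
    """
    _, rng = _rngs(cfg)
    X = covariate_matrix(persons, cfg.schema, cfg.true_joint.scaler)
    Xq = np.hstack([np.ones((len(persons), 1)), X])
    Bu, Bd, sig, rho = _coef_matrices(cfg.true_joint)
    U = Xq @ Bu
    U -= U.max(axis=1, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=1, keepdims=True)
    MU = Xq @ Bd  # (n, 3)

    n_trips = np.array([sum(int(p.counts.get(m, 0)) for m in MODES) for p in persons])
    idx = np.repeat(np.arange(len(persons)), n_trips)
    N = len(idx)
    if N == 0:
        return []

    cum = np.cumsum(P[idx], axis=1)
    mode_i = (rng.random(N)[:, None] > cum).sum(axis=1)
    p_chosen = P[idx, mode_i]
    e = ndtri(np.clip(rng.random(N) * p_chosen, 1e-300, 1 - 1e-16))
    rho_c = rho[mode_i]
    score = rho_c * e + np.sqrt(1.0 - rho_c**2) * rng.standard_normal(N)
    lnd = MU[idx, mode_i] + sig[mode_i] * score

    trips = []
    for t in range(N):
        p = persons[idx[t]]
        trips.append(
            TripRecord(
                person_id=p.person_id,
                mode=MODES[mode_i[t]],
                distance_m=float(np.exp(lnd[t])),
                covariates=p.covariates,
                home_xy=p.home_xy,
                cbd_distance_km=p.cbd_distance_km,
            )
        )
    return trips


# ---------------------------------------------------------------------------
# Default configurations
# ---------------------------------------------------------------------------


def coef_vector(
    schema: CovariateSchema, mapping: Mapping[str, float], const: float | None = None
) -> np.ndarray:
    """Build a coefficient vector over (encoded covariates + trend terms)
    from a name -> value mapping; unnamed entries are zero.  With ``const``
    a leading intercept is prepended (joint-model layout)."""
    names = (*schema.encoded_names, *TREND_NAMES)
    unknown = set(mapping) - set(names)
    if unknown:
        raise ConfigurationError(f"unknown coefficient name(s): {sorted(unknown)}")
    vec = np.array([float(mapping.get(n, 0.0)) for n in names])
    if const is not None:
        vec = np.concatenate([[const], vec])
    return vec


#: City used by the default configurations: 30 km x 20 km, 250 m cells,
#: CBD off-centre (as in most river-bound North American downtowns).
DEFAULT_CITY = GridSpec(
    origin_xy=(0.0, 0.0), n_rows=80, n_cols=120, cbd_xy=(8000.0, 10000.0), cell_size=250.0
)

#: Analytic scaler of the uniform home distribution over the default city
#: (mean = centre; SD of U(0, L) is L / sqrt(12) per axis).
DEFAULT_SCALER = CoordinateScaler(
    center_xy=(15000.0, 10000.0),
    scale_xy=(30000.0 / np.sqrt(12.0), 20000.0 / np.sqrt(12.0)),
)

_R_DEFAULT = np.array(
    [[1.0, -0.474, -0.231], [-0.474, 1.0, -0.656], [-0.231, -0.656, 1.0]]
)


def _full_schema() -> CovariateSchema:
    return CovariateSchema(
        (
            Categorical("age", ("55-64", "65-74", "75+"), "55-64"),
            Categorical("gender", ("female", "male"), "female"),
            Categorical("household", ("single", "couple", "other"), "single"),
            Categorical("occupation", ("retired", "working", "at-home"), "retired"),
            Categorical("income", ("<40k", "40-80k", ">80k"), "<40k"),
            Categorical("licence", ("no", "yes"), "no"),
            Categorical("vehicles", ("0", "1", "2+"), "0"),
            Continuous("act_density"),
        )
    )


def _full_generators() -> dict:
    return {
        "age": CategoricalGenerator((0.40, 0.35, 0.25)),
        "gender": CategoricalGenerator((0.55, 0.45)),
        "household": CategoricalGenerator((0.30, 0.55, 0.15)),
        "occupation": CategoricalGenerator((0.65, 0.25, 0.10)),
        "income": CategoricalGenerator((0.45, 0.35, 0.20)),
        "licence": CategoricalGenerator((0.25, 0.75)),
        "vehicles": CategoricalGenerator((0.30, 0.50, 0.20)),
        "act_density": ContinuousGenerator(mean=1.5, sd=0.5, cbd_slope=-0.06),
    }


def _full_joint(schema: CovariateSchema) -> JointModelParams:
    zero = coef_vector(schema, {}, const=0.0)
    util_walk = coef_vector(
        schema,
        {
            "age[65-74]": -0.10, "age[75+]": -0.25,
            "occupation[working]": -0.20,
            "licence[yes]": -0.60,
            "vehicles[1]": -1.00, "vehicles[2+]": -1.60,
            "act_density": 0.25,
            "trend:cbd_km": -0.030,
            "trend:x2": -0.03, "trend:y2": -0.03,
        },
        const=0.29,
    )
    util_transit = coef_vector(
        schema,
        {
            "age[65-74]": -0.05, "age[75+]": -0.15,
            "occupation[working]": 0.15,
            "licence[yes]": -0.70,
            "vehicles[1]": -1.10, "vehicles[2+]": -1.80,
            "act_density": 0.30,
            "trend:cbd_km": -0.020,
        },
        const=0.28,
    )
    dist_walk = coef_vector(
        schema,
        {
            "age[65-74]": -0.13, "age[75+]": -0.22,
            "gender[male]": 0.03,
            "household[couple]": 0.08, "household[other]": 0.11,
            "occupation[working]": -0.18, "occupation[at-home]": -0.01,
            "income[40-80k]": 0.05, "income[>80k]": 0.30,
            "licence[yes]": 0.08,
            "vehicles[1]": -0.36, "vehicles[2+]": -0.59,
            "act_density": -0.15,
            "trend:x": -0.05, "trend:y": 0.03,
            "trend:x2": 0.02, "trend:y2": 0.02,
            "trend:cbd_km": 0.012,
        },
        const=5.44,
    )
    dist_car = coef_vector(
        schema,
        {
            "age[65-74]": -0.06, "age[75+]": -0.15,
            "gender[male]": -0.11,
            "household[couple]": -0.05,
            "occupation[working]": 0.30,
            "income[40-80k]": 0.06, "income[>80k]": 0.10,
            "licence[yes]": 0.12,
            "vehicles[1]": 0.40, "vehicles[2+]": 0.60,
            "act_density": -0.05,
            "trend:cbd_km": 0.020,
        },
        const=7.25,
    )
    dist_transit = coef_vector(
        schema,
        {
            "age[65-74]": -0.10, "age[75+]": -0.30,
            "occupation[working]": 0.35,
            "licence[yes]": -0.02,
            "vehicles[1]": -0.27, "vehicles[2+]": -0.42,
            "act_density": 0.02,
            "trend:cbd_km": 0.030,
        },
        const=7.48,
    )
    return JointModelParams(
        utility_coefs={"walk": util_walk, "car": zero * 0.0, "transit": util_transit},
        distance_coefs={"walk": dist_walk, "car": dist_car, "transit": dist_transit},
        sigma={m: 1.084 for m in MODES},
        rho={m: -0.472 for m in MODES},
        schema=schema,
        scaler=DEFAULT_SCALER,
        reference_mode="car",
    )


def _full_freq(schema: CovariateSchema) -> OrderedProbitParams:
    walk = coef_vector(
        schema,
        {
            "age[65-74]": -0.09, "age[75+]": -0.13,
            "household[couple]": -0.07, "household[other]": -0.12,
            "occupation[working]": -0.30,
            "income[40-80k]": -0.05, "income[>80k]": 0.11,
            "licence[yes]": -0.21,
            "vehicles[1]": -0.39, "vehicles[2+]": -0.63,
            "act_density": 0.12,
            "trend:x2": 0.02, "trend:y2": 0.02, "trend:cbd_km": -0.020,
        },
    )
    car = coef_vector(
        schema,
        {
            "age[65-74]": 0.09, "age[75+]": 0.14,
            "gender[male]": -0.07,
            "household[couple]": -0.10, "household[other]": -0.22,
            "occupation[working]": -0.07,
            "income[40-80k]": 0.14, "income[>80k]": 0.20,
            "licence[yes]": 0.48,
            "vehicles[1]": 0.95, "vehicles[2+]": 1.15,
            "act_density": -0.08,
            "trend:cbd_km": 0.012,
        },
    )
    transit = coef_vector(
        schema,
        {
            "age[65-74]": -0.06, "age[75+]": -0.24,
            "gender[male]": 0.10,
            "household[other]": 0.21,
            "occupation[working]": 0.25,
            "income[>80k]": -0.10,
            "licence[yes]": -0.37,
            "vehicles[1]": -0.70, "vehicles[2+]": -0.95,
            "act_density": 0.10,
            "trend:cbd_km": -0.010,
        },
    )
    return OrderedProbitParams(
        coefs={"walk": walk, "car": car, "transit": transit},
        thresholds={
            "walk": np.array([-0.45, 0.10, 0.75]),
            "car": np.array([0.75, 1.25, 1.95]),
            "transit": np.array([-0.30, 0.15, 0.75]),
        },
        corr=_R_DEFAULT.copy(),
        schema=schema,
        scaler=DEFAULT_SCALER,
    )


def _compact_schema() -> CovariateSchema:
    return CovariateSchema(
        (
            Categorical("licence", ("no", "yes"), "no"),
            Continuous("act_density"),
        )
    )


def _compact_generators() -> dict:
    return {
        "licence": CategoricalGenerator((0.4, 0.6)),
        "act_density": ContinuousGenerator(mean=1.5, sd=0.5, cbd_slope=-0.06),
    }


def _compact_joint(schema: CovariateSchema) -> JointModelParams:
    zero = coef_vector(schema, {}, const=0.0)
    return JointModelParams(
        utility_coefs={
            "walk": coef_vector(
                schema,
                {"licence[yes]": -0.6, "act_density": 0.25, "trend:cbd_km": -0.03},
                const=-0.69,
            ),
            "car": zero * 0.0,
            "transit": coef_vector(
                schema,
                {"licence[yes]": -0.7, "act_density": 0.30, "trend:cbd_km": -0.02},
                const=-0.64,
            ),
        },
        distance_coefs={
            "walk": coef_vector(
                schema,
                {"licence[yes]": 0.08, "act_density": -0.15,
                 "trend:x": -0.05, "trend:x2": 0.02, "trend:cbd_km": 0.012},
                const=5.40,
            ),
            "car": coef_vector(
                schema,
                {"licence[yes]": 0.25, "act_density": -0.05, "trend:cbd_km": 0.02},
                const=7.53,
            ),
            "transit": coef_vector(
                schema,
                {"licence[yes]": -0.02, "act_density": 0.02, "trend:cbd_km": 0.03},
                const=7.30,
            ),
        },
        sigma={m: 1.084 for m in MODES},
        rho={m: -0.472 for m in MODES},
        schema=schema,
        scaler=DEFAULT_SCALER,
        reference_mode="car",
    )


def _compact_freq(schema: CovariateSchema) -> OrderedProbitParams:
    return OrderedProbitParams(
        coefs={
            "walk": coef_vector(
                schema, {"licence[yes]": -0.25, "act_density": 0.12, "trend:cbd_km": -0.02}
            ),
            "car": coef_vector(
                schema, {"licence[yes]": 0.55, "act_density": -0.08, "trend:cbd_km": 0.012}
            ),
            "transit": coef_vector(
                schema, {"licence[yes]": -0.40, "act_density": 0.10, "trend:cbd_km": -0.01}
            ),
        },
        thresholds={
            "walk": np.array([-0.50, 0.05, 0.70]),
            "car": np.array([-0.10, 0.40, 1.10]),
            "transit": np.array([-0.45, 0.00, 0.60]),
        },
        corr=_R_DEFAULT.copy(),
        schema=schema,
        scaler=DEFAULT_SCALER,
    )


def make_default_config(
    n_persons: int, seed: int, schema: str = "full"
) -> SimulationConfig:
    """A ready-to-run simulation configuration.

    ``schema="full"`` is the survey-like default (age, gender, household,
    occupation, income, licence, vehicles, activity density);
    ``schema="compact"`` keeps the same error structure over two covariates
    only, for fast estimator studies.
    """
    if n_persons < 1:
        raise ConfigurationError("n_persons must be >= 1")
    if schema == "full":
        sc = _full_schema()
        return SimulationConfig(
            n_persons=n_persons,
            seed=seed,
            true_joint=_full_joint(sc),
            true_freq=_full_freq(sc),
            city=DEFAULT_CITY,
            covariate_generators=_full_generators(),
        )
    if schema == "compact":
        sc = _compact_schema()
        return SimulationConfig(
            n_persons=n_persons,
            seed=seed,
            true_joint=_compact_joint(sc),
            true_freq=_compact_freq(sc),
            city=DEFAULT_CITY,
            covariate_generators=_compact_generators(),
        )
    raise ConfigurationError(f"unknown schema preset {schema!r}")
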