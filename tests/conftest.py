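"""Shared fixtures.

The parameter-recovery studies (20 seeds each) are session-scoped so the
acceptance tests and the module tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpmap.data_model import MODES, Categorical, Continuous, CovariateSchema
from cpmap.joint_distance_model import (
    JointModelParams,
    fit_joint,
    params_to_vector as joint_params_to_vector,
    rho_zero_lr_test,
)
from cpmap.ordered_frequency_model import (
    OrderedProbitParams,
    fit_frequency,
    params_to_vector as freq_params_to_vector,
)
from cpmap.synthetic_data import make_default_config, simulate_persons, simulate_trips

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: Study sizes for the recovery harnesses: ~5000 observations for each
#: estimator (trips for the joint model, persons for the frequency model).
N_SEEDS = 20
JOINT_N_PERSONS = 1400  # about 5200 trips under the compact preset
FREQ_N_PERSONS = 5000


@pytest.fixture(scope="session")
def small_schema() -> CovariateSchema:
    return CovariateSchema(
        (
            Categorical("income", ("<20k", "20-40k", "40-60k", ">60k"), "<20k"),
            Categorical("licence", ("no", "yes"), "no"),
            Continuous("density"),
        )
    )


def _zero_rho(params: JointModelParams) -> JointModelParams:
    return JointModelParams(
        utility_coefs={m: params.utility_coefs[m].copy() for m in MODES},
        distance_coefs={m: params.distance_coefs[m].copy() for m in MODES},
        sigma=dict(params.sigma),
        rho={m: 0.0 for m in MODES},
        schema=params.schema,
        scaler=params.scaler,
        reference_mode=params.reference_mode,
    )


def _identity_corr(params: OrderedProbitParams) -> OrderedProbitParams:
    return OrderedProbitParams(
        coefs={m: params.coefs[m].copy() for m in MODES},
        thresholds={m: params.thresholds[m].copy() for m in MODES},
        corr=np.eye(3),
        schema=params.schema,
        scaler=params.scaler,
    )


@pytest.fixture(scope="session")
def joint_recovery():
    """20-seed recovery study for the joint model (true correlated errors)."""
    out = []
    for seed in range(N_SEEDS):
        cfg = make_default_config(JOINT_N_PERSONS, 1000 + seed, schema="compact")
        persons = simulate_persons(cfg)
        trips = simulate_trips(persons, cfg)
        res = fit_joint(
            trips, cfg.schema, scaler=cfg.true_joint.scaler, compute_null=False
        )
        out.append((res, joint_params_to_vector(cfg.true_joint)))
    return out


#: The correlation of the selection model is weakly identified without
#: exclusion restrictions; its likelihood-ratio test calibrates at somewhat
#: larger samples than the coefficient-recovery study needs.
RHO0_N_PERSONS = 2500


@pytest.fixture(scope="session")
def joint_rho0_recovery():
    """20-seed study with rho = 0 in the generating process.

    Returns (LR statistic, p-value) of the rho = 0 likelihood-ratio test
    per seed.
    """
    out = []
    for seed in range(N_SEEDS):
        cfg = make_default_config(RHO0_N_PERSONS, 2000 + seed, schema="compact")
        cfg.true_joint = _zero_rho(cfg.true_joint)
        persons = simulate_persons(cfg)
        trips = simulate_trips(persons, cfg)
        res = fit_joint(
            trips, cfg.schema, scaler=cfg.true_joint.scaler,
            compute_se=False, compute_null=False,
        )
        out.append(
            rho_zero_lr_test(trips, cfg.schema, scaler=cfg.true_joint.scaler, fit=res)
        )
    return out


@pytest.fixture(scope="session")
def freq_recovery():
    """20-seed recovery study for the trivariate ordered probit."""
    out = []
    for seed in range(N_SEEDS):
        cfg = make_default_config(FREQ_N_PERSONS, 3000 + seed, schema="compact")
        persons = simulate_persons(cfg)
        res = fit_frequency(
            persons, cfg.schema, scaler=cfg.true_freq.scaler, compute_null=False
        )
        out.append((res, freq_params_to_vector(cfg.true_freq)))
    return out


@pytest.fixture(scope="session")
def freq_identity_recovery():
    """20-seed study with R = I in the generating process."""
    out = []
    for seed in range(N_SEEDS):
        cfg = make_default_config(FREQ_N_PERSONS, 4000 + seed, schema="compact")
        cfg.true_freq = _identity_corr(cfg.true_freq)
        persons = simulate_persons(cfg)
        res = fit_frequency(
            persons, cfg.schema, scaler=cfg.true_freq.scaler,
            compute_se=False, compute_null=False,
        )
        out.append(res)
    return out
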