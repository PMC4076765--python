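"""Joint discrete-continuous model: probabilities, likelihood, estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import dblquad
from scipy.special import ndtri
from scipy.stats import lognorm

from cpmap.data_model import MODES, CovariateSchema, TripRecord
from cpmap.errors import EstimationError, ParameterDomainError
from cpmap.joint_distance_model import (
    JointModelParams,
    fit_joint,
    joint_loglik,
    mnl_probabilities,
    predict_distance,
)
from cpmap.synthetic_data import make_default_config, simulate_persons, simulate_trips
from cpmap.trend_surface import CoordinateScaler, TrendTerms


EMPTY_SCHEMA = CovariateSchema(())
UNIT_SCALER = CoordinateScaler((0.0, 0.0), (1.0, 1.0))


def _const_params(u_walk=0.0, u_transit=0.0, mu=None, sigma=1.0, rho=0.0):
    """Location-independent parameters: only intercepts are nonzero."""
    mu = mu or {"walk": 6.0, "car": 8.0, "transit": 8.0}
    vec = lambda c: np.array([c, 0, 0, 0, 0, 0, 0.0])
    return JointModelParams(
        utility_coefs={"walk": vec(u_walk), "car": vec(0.0) * 0, "transit": vec(u_transit)},
        distance_coefs={m: vec(mu[m]) for m in MODES},
        sigma={m: sigma for m in MODES},
        rho={m: rho for m in MODES},
        schema=EMPTY_SCHEMA,
        scaler=UNIT_SCALER,
    )


def _trip(mode="walk", d=500.0):
    return TripRecord(
        person_id="p", mode=mode, distance_m=d, covariates={},
        home_xy=(0.0, 0.0), cbd_distance_km=0.0,
    )


class TestMnlProbabilities:
    def test_equal_utilities_give_thirds(self):
        p = mnl_probabilities(np.zeros(6), _const_params())
        assert all(v == pytest.approx(1 / 3) for v in p.values())

    def test_log_two_utility_gives_quarter_quarter_half(self):
        p = mnl_probabilities(np.zeros(6), _const_params(u_walk=math.log(2)))
        assert p["walk"] == pytest.approx(0.5)
        assert p["car"] == pytest.approx(0.25)
        assert p["transit"] == pytest.approx(0.25)

    def test_extreme_utility_saturates_without_nan(self):
        p = mnl_probabilities(np.zeros(6), _const_params(u_walk=1000.0))
        assert p["walk"] == pytest.approx(1.0, abs=1e-10)
        assert p["car"] >= 0.0 and np.isfinite(list(p.values())).all()

    @given(uw=st.floats(-30, 30), ut=st.floats(-30, 30))
    def test_probabilities_positive_and_sum_to_one(self, uw, ut):
        p = mnl_probabilities(np.zeros(6), _const_params(u_walk=uw, u_transit=ut))
        assert all(v > 0 for v in p.values())
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


class TestJointLoglik:
    def test_factorizes_at_zero_rho(self):
        params = _const_params(u_walk=0.7, u_transit=-0.4, sigma=1.1, rho=0.0)
        trips = [_trip("walk", 400.0), _trip("car", 9000.0), _trip("transit", 1500.0)]
        ll = joint_loglik(trips, params)
        expected = 0.0
        for t in trips:
            p = mnl_probabilities(np.zeros(6), params)[t.mode]
            mu = params.distance_coefs[t.mode][0]
            expected += math.log(p) + lognorm.logpdf(
                t.distance_m, s=params.sigma[t.mode], scale=math.exp(mu)
            )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_duplicating_trips_doubles_loglik_exactly(self):
        params = _const_params(u_walk=0.3, sigma=0.9, rho=-0.5)
        trips = [_trip("walk", 350.0), _trip("car", 5000.0)]
        assert joint_loglik(trips + trips, params) == 2.0 * joint_loglik(trips, params)

    def test_matches_bivariate_quadrature_oracle(self):
        # brute-force: the joint density of (mode m, distance d) is the
        # d-derivative of P(alpha <= u, eps <= ndtri(P_m)) under the
        # correlated bivariate normal, computed here by numerically
        # differentiating a 2-D integral of the bivariate normal pdf.
        rng = np.random.default_rng(10)
        for _ in range(25):
            rho = rng.uniform(-0.9, 0.9)
            sigma = rng.uniform(0.5, 1.5)
            params = _const_params(
                u_walk=rng.uniform(-1.5, 1.5), u_transit=rng.uniform(-1.5, 1.5),
                mu={"walk": rng.uniform(5.5, 6.5), "car": 8.0, "transit": 8.0},
                sigma=sigma, rho=rho,
            )
            mode = ("walk", "car", "transit")[rng.integers(0, 3)]
            d = float(rng.uniform(150, 3000))
            ll = joint_loglik([_trip(mode, d)], params)

            P_m = mnl_probabilities(np.zeros(6), params)[mode]
            c = ndtri(P_m)
            mu_m = params.distance_coefs[mode][0]
            u = (math.log(d) - mu_m) / sigma
            s2 = 1.0 - rho * rho

            def pdf(e, a):
                z = (a * a - 2 * rho * a * e + e * e) / s2
                return math.exp(-0.5 * z) / (2 * math.pi * math.sqrt(s2))

            def G(uu):
                val, _ = dblquad(pdf, -8.5, uu, -8.5, c, epsabs=1e-12, epsrel=1e-10)
                return val

            h = 1e-3  # fourth-order stencil: truncation O(h^4) ~ 1e-12
            dens = (
                (G(u - 2 * h) - 8 * G(u - h) + 8 * G(u + h) - G(u + 2 * h))
                / (12 * h)
                / (sigma * d)
            )
            assert ll == pytest.approx(math.log(dens), abs=1e-6)

    def test_parameter_domain_errors(self):
        with pytest.raises(ParameterDomainError):
            _const_params(sigma=-1.0)
        with pytest.raises(ParameterDomainError):
            _const_params(rho=1.0)


class TestPredictDistance:
    def test_lognormal_mean_correction(self):
        params = _const_params(mu={"walk": math.log(500.0), "car": 8.0, "transit": 8.0},
                               sigma=0.5)
        t = TrendTerms(0, 0, 0, 0, 0, 0)
        got = predict_distance(np.zeros(0), t, params, "walk")
        assert got == pytest.approx(500.0 * math.exp(0.125))
        assert predict_distance(np.zeros(0), t, params, "walk", kind="median") == (
            pytest.approx(500.0)
        )

    def test_zero_linear_predictor_small_sigma_approaches_one_metre(self):
        params = _const_params(mu={m: 0.0 for m in MODES}, sigma=1e-8)
        t = TrendTerms(0, 0, 0, 0, 0, 0)
        assert predict_distance(np.zeros(0), t, params, "walk") == pytest.approx(1.0)

    def test_monotone_in_coefficients(self):
        t = TrendTerms(0, 0, 0, 0, 0, 1.0)  # cbd term active
        lo = _const_params()
        hi = _const_params()
        hi.distance_coefs["walk"] = hi.distance_coefs["walk"].copy()
        hi.distance_coefs["walk"][-1] = 0.2  # positive coefficient on cbd
        assert predict_distance(np.zeros(0), t, hi, "walk") > predict_distance(
            np.zeros(0), t, lo, "walk"
        )


class TestFitJoint:
    def test_missing_mode_raises(self, small_schema):
        cfg = make_default_config(60, 5, schema="compact")
        trips = simulate_trips(simulate_persons(cfg), cfg)
        walk_only = [t for t in trips if t.mode == "walk"]
        with pytest.raises(EstimationError, match="mode"):
            fit_joint(walk_only, cfg.schema)

    def test_collinear_design_names_columns(self):
        cfg = make_default_config(150, 6, schema="compact")
        persons = simulate_persons(cfg)
        trips = simulate_trips(persons, cfg)
        # duplicate the continuous covariate under a second name
        from cpmap.data_model import Continuous, CovariateSchema, TripRecord

        sch = CovariateSchema((*cfg.schema.variables, Continuous("act_density_copy")))
        dup = [
            TripRecord(t.person_id, t.mode, t.distance_m,
                       {**t.covariates, "act_density_copy": t.covariates["act_density"]},
                       t.home_xy, t.cbd_distance_km)
            for t in trips
        ]
        with pytest.raises(EstimationError, match="collinear"):
            fit_joint(dup, sch)

    def test_fit_beats_constant_only_model(self):
        cfg = make_default_config(500, 12, schema="compact")
        trips = simulate_trips(simulate_persons(cfg), cfg)
        res = fit_joint(trips, cfg.schema, scaler=cfg.true_joint.scaler)
        assert res.converged
        assert res.loglik >= res.loglik_null
        assert res.n_obs == len(trips)
        assert np.isfinite(res.std_errors).all()

    def test_per_mode_scales_nest_the_pooled_model(self):
        cfg = make_default_config(500, 12, schema="compact")
        trips = simulate_trips(simulate_persons(cfg), cfg)
        pooled = fit_joint(trips, cfg.schema, scaler=cfg.true_joint.scaler,
                           compute_se=False, compute_null=False)
        free = fit_joint(trips, cfg.schema, scaler=cfg.true_joint.scaler,
                         pooled=False, compute_se=False, compute_null=False)
        assert len(set(free.params.sigma.values())) == 3
        assert free.loglik >= pooled.loglik - 1e-6  # nested models

    def test_params_json_roundtrip(self, tmp_path):
        cfg = make_default_config(5, 13, schema="compact")
        p = cfg.true_joint
        p.save(tmp_path / "m.json")
        q = JointModelParams.load(tmp_path / "m.json")
        for m in MODES:
            assert np.array_equal(p.utility_coefs[m], q.utility_coefs[m])
            assert np.array_equal(p.distance_coefs[m], q.distance_coefs[m])
            assert p.sigma[m] == q.sigma[m] and p.rho[m] == q.rho[m]
        assert q.schema.to_dict() == p.schema.to_dict()
        assert q.scaler == p.scaler


class TestParameterRecovery:
    def test_coefficients_recovered_within_three_se(self, joint_recovery):
        total = ok = 0
        for res, truth in joint_recovery:
            z = np.abs(res.coef_vector - truth) / res.std_errors
            total += len(z)
            ok += int((z <= 3.0).sum())
        assert ok / total >= 0.95

    def test_zero_rho_data_yields_insignificant_rho(self, joint_rho0_recovery):
        # likelihood-ratio test of rho = 0 at the 5% level
        n_ok = sum(int(p_value >= 0.05) for _, p_value in joint_rho0_recovery)
        assert n_ok >= 0.90 * len(joint_rho0_recovery)
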