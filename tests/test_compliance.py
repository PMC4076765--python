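"""Compliance map algebra: TDWD, WWM, percent-of-guideline, rasters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpmap.compliance import (
    GuidelineConfig,
    Profile,
    area_by_compliance,
    build_compliance_raster,
    compliance_percent,
    guideline_distance_km,
    tdwd,
    wwm,
)
from cpmap.data_model import GridSpec
from cpmap.errors import ConfigurationError, ParameterDomainError
from cpmap.joint_distance_model import predict_distance
from cpmap.ordered_frequency_model import marginal_class_probs
from cpmap.synthetic_data import make_default_config
from cpmap.trend_surface import trend_terms

CFG = GuidelineConfig()

probs4 = st.tuples(*[st.floats(0, 1) for _ in range(4)]).map(
    lambda t: np.array(t) / max(sum(t), 1e-9)
).filter(lambda p: abs(p.sum() - 1) < 1e-9)


class TestTdwd:
    def test_single_trip_class_returns_distance(self):
        assert tdwd(500.0, np.array([0, 1, 0, 0.0])) == pytest.approx(500.0)

    def test_weighted_sum_of_classes(self):
        # 800 * (1*0.5 + 2*0.3 + 3*0.2) = 1360
        assert tdwd(800.0, np.array([0, 0.5, 0.3, 0.2])) == pytest.approx(1360.0)

    def test_no_trips_gives_zero(self):
        assert tdwd(700.0, np.array([1, 0, 0, 0.0])) == 0.0

    def test_k_cap_bounds_result(self):
        assert tdwd(600.0, np.array([0, 0, 0, 1.0]), k_cap=5) == pytest.approx(3000.0)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ParameterDomainError):
            tdwd(500.0, np.array([0.5, 0.5, 0.5, 0.5]))

    @given(p=probs4, d=st.floats(1, 5000))
    def test_bounded_by_k_cap_times_distance(self, p, d):
        v = tdwd(d, p)
        assert 0.0 <= v <= 3.0 * d + 1e-9


class TestGuidelineArithmetic:
    def test_guideline_distance_is_ten_point_two_six_km(self):
        assert round(guideline_distance_km(CFG), 2) == 10.26

    def test_guideline_distance_general(self):
        assert guideline_distance_km(GuidelineConfig(100.0, 60.0, 5)) == pytest.approx(6.0)

    def test_wwm_reaches_guideline_at_equivalent_distance(self):
        # 2052 m/day * 5 days / 68.4 m/min = 150 min/week
        assert wwm(2052.0, CFG) == pytest.approx(150.0)
        assert wwm(0.0, CFG) == 0.0

    def test_wwm_linear_in_days(self):
        c2 = GuidelineConfig(days_per_week=10)
        assert wwm(1234.5, c2) == pytest.approx(2 * wwm(1234.5, CFG))

    def test_compliance_percent_not_capped(self):
        assert compliance_percent(150.0, CFG) == pytest.approx(100.0)
        assert compliance_percent(22.5, CFG) == pytest.approx(15.0)
        assert compliance_percent(300.0, CFG) == pytest.approx(200.0)
        assert compliance_percent(0.0, CFG) == 0.0

    def test_scale_consistency_of_speed_and_guideline(self):
        # doubling walking speed and halving guideline minutes leaves the
        # implied guideline distance unchanged
        a = guideline_distance_km(GuidelineConfig(150, 68.4, 5))
        b = guideline_distance_km(GuidelineConfig(75, 136.8, 5))
        assert a == pytest.approx(b)

    def test_positive_config_required(self):
        with pytest.raises(ParameterDomainError):
            GuidelineConfig(weekly_minutes=0.0)


@pytest.fixture(scope="module")
def models():
    cfg = make_default_config(10, 30, schema="compact")
    return cfg.true_joint, cfg.true_freq


@pytest.fixture(scope="module")
def profile():
    return Profile({"licence": "no", "act_density": 1.0}, name="carless senior")


class TestComplianceRaster:
    def test_single_cell_equals_hand_chained_pipeline(self, models, profile):
        dist_model, freq_model = models
        grid = GridSpec((4000.0, 6000.0), 1, 1, (8000.0, 10000.0), cell_size=250.0)
        raster = build_compliance_raster(profile, dist_model, freq_model, grid, CFG)

        xy = grid.centroids()[0, 0]
        design = dist_model.schema.encode(profile.covariates)
        d_hat = predict_distance(
            design, trend_terms(xy, dist_model.scaler, grid.cbd_xy), dist_model, "walk"
        )
        probs = marginal_class_probs(
            design, trend_terms(xy, freq_model.scaler, grid.cbd_xy), freq_model, "walk"
        )
        t = tdwd(d_hat, probs)
        w = wwm(t, CFG)
        c = compliance_percent(w, CFG)
        assert raster.layers["d_hat"][0, 0] == pytest.approx(d_hat, rel=1e-12)
        assert raster.layers["p1"][0, 0] == pytest.approx(probs[1], rel=1e-12)
        assert raster.layers["tdwd"][0, 0] == pytest.approx(t, rel=1e-12)
        assert raster.layers["wwm"][0, 0] == pytest.approx(w, rel=1e-12)
        assert raster.layers["compliance"][0, 0] == pytest.approx(c, rel=1e-12)

    def test_layers_finite_nonnegative_and_reconstruct_tdwd(self, models, profile):
        dist_model, freq_model = models
        grid = GridSpec((0.0, 0.0), 6, 9, (8000.0, 10000.0), cell_size=500.0)
        raster = build_compliance_raster(profile, dist_model, freq_model, grid, CFG)
        for name, layer in raster.layers.items():
            assert layer.shape == grid.shape
            assert np.isfinite(layer).all()
            assert (layer >= 0).all(), name
        for p in ("p1", "p2", "p3plus"):
            assert (raster.layers[p] <= 1).all()
        recon = raster.layers["d_hat"] * (
            raster.layers["p1"] + 2 * raster.layers["p2"] + 3 * raster.layers["p3plus"]
        )
        assert raster.layers["tdwd"] == pytest.approx(recon, rel=1e-12)

    def test_zero_coefficient_covariate_does_not_change_raster(self, models):
        dist_model, freq_model = models
        grid = GridSpec((0.0, 0.0), 2, 2, (8000.0, 10000.0), cell_size=1000.0)
        # licence has nonzero coefficients, act_density shift of 0 is neutral;
        # two profiles identical except a covariate whose coefficients are all
        # zero would need such a covariate: use act_density with zeroed coefs
        import copy

        dm = copy.deepcopy(dist_model)
        fm = copy.deepcopy(freq_model)
        j = list(dm.schema.encoded_names).index("act_density")
        for m in ("walk", "car", "transit"):
            dm.distance_coefs[m][1 + j] = 0.0
            dm.utility_coefs[m][1 + j] = 0.0
            fm.coefs[m][j] = 0.0
        p1 = Profile({"licence": "no", "act_density": 0.3})
        p2 = Profile({"licence": "no", "act_density": 2.7})
        r1 = build_compliance_raster(p1, dm, fm, grid, CFG)
        r2 = build_compliance_raster(p2, dm, fm, grid, CFG)
        for name in r1.layers:
            assert np.array_equal(r1.layers[name], r2.layers[name])

    def test_schema_mismatch_raises(self, models, profile):
        dist_model, freq_model = models
        other = make_default_config(5, 31, schema="full")
        grid = GridSpec((0.0, 0.0), 1, 1, (0.0, 0.0))
        with pytest.raises(ConfigurationError):
            build_compliance_raster(profile, dist_model, other.true_freq, grid, CFG)

    def test_csv_and_ascii_outputs(self, models, profile, tmp_path):
        dist_model, freq_model = models
        grid = GridSpec((0.0, 0.0), 3, 4, (8000.0, 10000.0), cell_size=250.0)
        raster = build_compliance_raster(profile, dist_model, freq_model, grid, CFG)
        raster.write_csv(tmp_path / "r.csv")
        paths = raster.write_ascii_grids(tmp_path / "r")
        assert len(paths) == 7
        txt = open(paths[0]).read().splitlines()
        assert txt[0].split() == ["ncols", "4"]
        assert txt[1].split() == ["nrows", "3"]
        # .asc rows run north->south: first data row is the top grid row
        top = np.array([float(v) for v in txt[6].split()])
        assert top == pytest.approx(raster.layers["d_hat"][-1])
        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert len(df) == 12
        assert df["compliance_pct"].to_numpy() == pytest.approx(
            raster.layers["compliance"].ravel()
        )


class TestAreaHistogram:
    def _raster(self, models, profile, n_rows=2, n_cols=2, cell=250.0):
        dist_model, freq_model = models
        grid = GridSpec((0.0, 0.0), n_rows, n_cols, (8000.0, 10000.0), cell_size=cell)
        return build_compliance_raster(profile, dist_model, freq_model, grid, CFG)

    def test_four_cells_in_one_bin_hold_quarter_km2(self, models, profile):
        raster = self._raster(models, profile)
        hist = area_by_compliance(raster, [-1e9, 1e9])
        assert hist.area_km2.sum() == pytest.approx(0.25)
        assert hist.underflow == hist.overflow == 0.0

    def test_total_area_conserved_for_any_edges(self, models, profile):
        raster = self._raster(models, profile, 3, 5)
        for edges in ([0, 1], [0, 5, 10, 100], [2.5, 2.6]):
            hist = area_by_compliance(raster, edges)
            assert hist.total_km2 == pytest.approx(15 * 0.0625)

    def test_bins_below_all_values_are_zero(self, models, profile):
        raster = self._raster(models, profile)
        hist = area_by_compliance(raster, [-100.0, -50.0])
        assert np.all(hist.area_km2 == 0.0)
        assert hist.overflow == pytest.approx(0.25)

    def test_mask_restricts_area(self, models, profile):
        raster = self._raster(models, profile, 2, 2)
        mask = np.array([[True, False], [False, False]])
        hist = area_by_compliance(raster, [-1e9, 1e9], mask=mask)
        assert hist.total_km2 == pytest.approx(0.0625)

    def test_bad_edges_rejected(self, models, profile):
        raster = self._raster(models, profile)
        with pytest.raises(ParameterDomainError):
            area_by_compliance(raster, [1.0, 1.0])
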