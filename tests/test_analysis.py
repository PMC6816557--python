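import numpy as np
import pandas as pd
import pytest

from ecmflock.analysis import (
    _rng_for,
    _simulated_persistence,
    aligned_substrate,
    calibrate_feedback,
    calibrate_noise,
    pca_summary,
    persistence,
    population_persistence,
    remodeling_experiment,
    run_sweep,
    smooth_track,
)
from ecmflock.params import SimulationParams


def straight_track(n=20, speed=3.0):
    return np.column_stack([np.arange(n) * speed, np.zeros(n)])


class TestPersistence:
    def test_straight_line_is_one(self):
        for speed in (0.5, 1.0, 7.0):
            assert persistence(straight_track(speed=speed), 5) == 1.0

    def test_straight_line_survives_smoothing(self):
        assert persistence(straight_track(40), 5, smooth=True) > 0.999

    def test_closed_loop_is_zero(self):
        loop = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert persistence(loop, 4) == 0.0

    def test_right_angle_path(self):
        # two equal legs of length 2: net sqrt(2)*2 over path 4
        L = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]], float)
        assert np.isclose(persistence(L, 4), 1 / np.sqrt(2))

    def test_stationary_track_is_one(self):
        assert persistence(np.zeros((10, 2)), 4) == 1.0

    def test_bounded_in_unit_interval(self, rng):
        walk = np.cumsum(rng.normal(size=(200, 2)), axis=0)
        p = persistence(walk, 8)
        assert 0.0 <= p <= 1.0

    def test_literal_denominator_variant_differs(self):
        L = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]], float)
        lit = persistence(L, 4, literal_denominator=True)
        assert lit != persistence(L, 4)
        assert 0 <= lit <= 1

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            persistence(straight_track(4), 4)

    def test_population_mean_over_cells(self):
        tracks = np.stack([straight_track(10), straight_track(10)], axis=1)
        assert population_persistence(tracks, 4) == 1.0


def test_smooth_track_preserves_straight_lines():
    t = straight_track(30)
    assert np.allclose(smooth_track(t), t, atol=1e-6)


class TestRunSweep:
    BASE = SimulationParams(n_cells=10, grid_shape=(20, 20),
                            domain_size=(200.0, 200.0), duration_days=0.25)

    def test_single_condition_single_rep(self):
        df = run_sweep([{"w_m": 0.1}], self.BASE, reps=1)
        assert len(df) == 1
        assert {"lra", "sra", "hdm", "curv", "frac"} <= set(df.columns)

    def test_deterministic_under_base_seed(self):
        a = run_sweep([{}, {"w_c": 0.1}], self.BASE, reps=2, base_seed=3)
        b = run_sweep([{}, {"w_c": 0.1}], self.BASE, reps=2, base_seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_condition_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipping"):
            df = run_sweep([{"w_c": 0.6, "w_m": 0.6}, {}], self.BASE, reps=1)
        assert len(df) == 1

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([], self.BASE)


class TestPCASummary:
    def test_perfectly_correlated_metrics(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"lra": x, "sra": 2 * x, "hdm": -x,
                           "curv": 3 * x, "frac": 0.5 * x})
        s = pca_summary(df)
        assert np.isclose(s.variance_ratio[0], 1.0)
        assert s.first_two_variance_pct == pytest.approx(100.0)

    def test_isotropic_noise_splits_evenly(self, rng):
        df = pd.DataFrame(rng.normal(size=(20_000, 5)),
                          columns=["lra", "sra", "hdm", "curv", "frac"])
        s = pca_summary(df)
        assert np.allclose(s.variance_ratio, 0.2, atol=0.02)

    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"lra": rng.normal(size=30), "sra": rng.normal(size=30),
                           "hdm": np.ones(30), "curv": rng.normal(size=30),
                           "frac": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            s = pca_summary(df)
        assert "hdm" in s.dropped
        assert list(s.loadings.index) == ["lra", "sra", "curv", "frac"]

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"lra": [1, 2], "sra": [1, 2], "hdm": [1, 2],
                           "curv": [1, 2], "frac": [1, 2]})
        with pytest.raises(ValueError):
            pca_summary(df)


class TestCalibration:
    def test_perfect_persistence_selects_zero_noise(self):
        est = calibrate_noise([1.0, 1.0], [0.0, 0.1, 0.3], n_cells=5)
        assert est == 0.0

    def test_single_candidate(self):
        assert calibrate_noise([0.8, 0.7], [0.13], n_cells=5) == 0.13

    def test_noise_recovery_on_synthetic_observations(self):
        grid = [0.02, 0.07, 0.13, 0.25]
        base = SimulationParams()
        obs = _simulated_persistence(
            base.evolve(noise_variance=0.13, w_c=0.0, w_m=0.0, n_cells=15),
            (2, 4), _rng_for(42, 0))
        assert calibrate_noise(obs, grid, n_cells=15, base_seed=7) == 0.13

    def test_feedback_recovery_and_monotonicity(self):
        base = SimulationParams()
        sub = aligned_substrate(base)
        frozen = dict(w_c=0.0, n_cells=15, deposition_rate=0.0,
                      degradation_rate=0.0, rearrangement_rate=0.0)
        obs = _simulated_persistence(
            base.evolve(noise_variance=0.13, w_m=0.27, **frozen),
            (2, 4), _rng_for(43, 0), substrate=sub)
        grid = [0.0, 0.1, 0.27, 0.5]
        assert calibrate_feedback(obs, 0.13, grid, substrate=sub,
                                  n_cells=15, base_seed=7) == 0.27
        # persistence on an aligned substrate is non-decreasing in w_m
        pers = [
            _simulated_persistence(
                base.evolve(noise_variance=0.13, w_m=wm, **frozen),
                (4,), _rng_for(44, int(100 * wm)), substrate=sub)[0]
            for wm in (0.0, 0.3, 0.8)
        ]
        assert pers[0] <= pers[1] <= pers[2]

    def test_zero_feedback_observations_select_zero(self):
        base = SimulationParams()
        sub = aligned_substrate(base)
        obs = _simulated_persistence(
            base.evolve(noise_variance=0.13, w_c=0.0, w_m=0.0, n_cells=15,
                        deposition_rate=0.0, degradation_rate=0.0,
                        rearrangement_rate=0.0),
            (2, 4), _rng_for(45, 0), substrate=sub)
        assert calibrate_feedback(obs, 0.13, [0.0, 0.4, 0.8], substrate=sub,
                                  n_cells=15, base_seed=9) == 0.0


class TestRemodeling:
    PHASE1 = SimulationParams(n_cells=20, grid_shape=(30, 30),
                              domain_size=(300.0, 300.0))

    def test_switch_day_validation(self):
        with pytest.raises(ValueError):
            remodeling_experiment(self.PHASE1, {"a": {}}, switch_day=5, end_day=3)

    def test_null_condition_continues_phase_one(self):
        """Handing the grid to identically parameterized cells leaves the
        alignment trend statistically unchanged at the switch."""
        res = remodeling_experiment(self.PHASE1, {"null": {}},
                                    switch_day=1.0, end_day=2.0, reps=4,
                                    record_days=0.5)
        ts = res.timeseries.groupby("day").lra.mean()
        before = ts[ts.index <= 1.0].to_numpy()
        after = ts[ts.index > 1.0].to_numpy()
        assert abs(after.mean() - before.mean()) < 0.1

    def test_endpoint_table_and_ttest(self):
        res = remodeling_experiment(
            self.PHASE1, {"a": {}, "b": {"w_m": 0.2}},
            switch_day=0.5, end_day=1.0, reps=3, compare=("a", "b"),
            record_days=0.5)
        assert set(res.endpoints.condition) == {"a", "b"}
        assert len(res.endpoint_lra("a")) == 3
        assert 0 <= res.ttest["p"] <= 1
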