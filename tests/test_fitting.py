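"""Cost function, parameter-space semantics and the hybrid optimizer."""

import numpy as np
import pandas as pd
import pytest

from stat1kin import (
    ConfigurationError,
    Dataset,
    NoiseSpec,
    OptimizerSettings,
    ParameterSpace,
    ParamSpec,
    chi_squared,
    fit,
    generate_dataset,
    hybrid_minimize,
)
from stat1kin.fitting import PENALTY_COST, predict


@pytest.fixture()
def small_dataset(demo_params, demo_sf):
    """Single-dose, total-lysate-only synthetic dataset (fast to simulate)."""
    data = generate_dataset(
        demo_params,
        demo_sf,
        doses=(100.0,),
        times=(0.0, 60.0, 180.0, 360.0, 720.0),
        noise=NoiseSpec(seed=3),
        full_panel_doses=(),
    )
    return data.dataset


class TestChiSquared:
    def test_zero_at_truth_on_noiseless_data(self, noiseless_data, theta_star):
        space = __import__("stat1kin").demo_parameter_space()
        assert chi_squared(theta_star, noiseless_data.dataset, space) < 1e-10

    def test_single_two_sigma_residual_costs_four(
        self, noiseless_data, theta_star
    ):
        space = __import__("stat1kin").demo_parameter_space()
        frame = noiseless_data.dataset.frame.copy()
        row = frame.index[frame["observable"] == "RSNC"][3]
        frame.loc[row, "mean"] += 2.0 * frame.loc[row, "sem"]
        bumped = Dataset(frame, provenance="synthetic")
        theta = dict(theta_star, **noiseless_data.manifest["implied_gains"])
        assert chi_squared(theta, bumped, space) == pytest.approx(4.0, abs=1e-6)

    def test_equals_flat_loop_oracle(self, noisy_data, theta_star):
        space = __import__("stat1kin").demo_parameter_space()
        pred = predict(theta_star, noisy_data.dataset, space)
        oracle = 0.0
        for _, row in pred.iterrows():
            oracle += ((row["mean"] - row["prediction"]) / row["sem"]) ** 2
        got = chi_squared(theta_star, noisy_data.dataset, space)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_row_permutation(self, noisy_data, theta_star):
        space = __import__("stat1kin").demo_parameter_space()
        a = chi_squared(theta_star, noisy_data.dataset, space)
        shuffled = noisy_data.dataset.frame.sample(frac=1.0, random_state=4)
        b = chi_squared(theta_star, Dataset(shuffled, provenance="synthetic"), space)
        assert a == pytest.approx(b, rel=1e-12)

    def test_simulation_failure_returns_finite_penalty(
        self, small_dataset, demo_params
    ):
        # an enormous rate constant makes the integrator give up
        space = ParameterSpace(
            [ParamSpec("k_act", 1e-5, 1e300, scale="linear")], base=demo_params
        )
        cost = chi_squared({"k_act": 1e280}, small_dataset, space)
        assert cost == PENALTY_COST

    def test_explicit_gain_overrides_profiling(
        self, noiseless_data, theta_star, small_space
    ):
        ds = noiseless_data.dataset
        implied = noiseless_data.manifest["implied_gains"]["WB_STAT1D@100"]
        base = chi_squared(theta_star, ds, small_space)
        forced = chi_squared(
            dict(theta_star, **{"WB_STAT1D@100": implied * 10}), ds, small_space
        )
        assert forced > base + 1.0


class TestDatasetValidation:
    def test_zero_sem_rejected_with_row_index(self, small_dataset):
        frame = small_dataset.frame.copy()
        frame.loc[2, "sem"] = 0.0
        with pytest.raises(ConfigurationError, match=r"\[2\]"):
            Dataset(frame)

    def test_duplicate_rows_rejected(self, small_dataset):
        frame = pd.concat([small_dataset.frame, small_dataset.frame.iloc[[0]]])
        with pytest.raises(ConfigurationError, match="duplicate"):
            Dataset(frame.reset_index(drop=True))

    def test_unknown_observable_rejected(self, small_dataset):
        frame = small_dataset.frame.copy()
        frame.loc[0, "observable"] = "STAT3_total"
        with pytest.raises(ConfigurationError, match="STAT3_total"):
            Dataset(frame)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            Dataset(pd.DataFrame(columns=["observable", "dose_ng_ml",
                                          "time_min", "mean", "sem"]))

    def test_unknown_parameter_name_rejected(self, demo_params):
        with pytest.raises(ConfigurationError, match="k_bogus"):
            ParameterSpace([ParamSpec("k_bogus", 0.1, 1.0)], base=demo_params)


class TestHybridOptimizer:
    def test_recovers_quadratic_optimum(self):
        target = np.array([0.3, -1.2, 2.4])

        def cost(x):
            return float(np.sum((x - target) ** 2))

        def residual(x):
            return x - target

        settings = OptimizerSettings(
            n_restarts=2, sa_iterations=200, local_max_iterations=50,
            local_tolerance=1e-12, seed=1,
        )
        x, c, trace = hybrid_minimize(
            cost, np.full(3, -5.0), np.full(3, 5.0), settings, residual=residual
        )
        assert np.allclose(x, target, atol=1e-6)
        assert c < 1e-10

    def test_trace_is_monotone_non_increasing(self):
        def cost(x):
            return float(np.sum(x**2) + np.sin(5 * x).sum())

        settings = OptimizerSettings(n_restarts=3, sa_iterations=150, seed=2)
        _, _, trace = hybrid_minimize(
            cost, np.full(2, -3.0), np.full(2, 3.0), settings
        )
        assert np.all(np.diff(trace) <= 1e-12)

    def test_settings_validation(self):
        with pytest.raises(ConfigurationError):
            OptimizerSettings(sa_cooling_rate=1.5)
        with pytest.raises(ConfigurationError):
            OptimizerSettings(n_restarts=0)


class TestFit:
    def test_seeded_fit_is_deterministic(
        self, small_dataset, small_space, quick_settings
    ):
        a = fit(small_dataset, small_space, quick_settings)
        b = fit(small_dataset, small_space, quick_settings)
        assert a.chi2 == b.chi2
        assert a.theta == b.theta
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_result_cost_bounds_trace_and_is_reasonable(
        self, small_dataset, small_space, quick_settings
    ):
        res = fit(small_dataset, small_space, quick_settings)
        assert res.chi2 <= res.trace.min() + 1e-12
        assert res.chi2 / res.n_data < 5.0
        assert set(res.trajectories) == {100.0}
        # profiled gains are reported in theta_hat
        assert "WB_STAT1D@100" in res.theta

    def test_empty_space_rejected(self, small_dataset, demo_params):
        space = ParameterSpace(
            [ParamSpec("k_act", fixed=True, value=5e-4)], base=demo_params
        )
        with pytest.raises(ConfigurationError, match="free"):
            fit(small_dataset, space)

    def test_local_scope_fits_dose_specific_truth_at_least_as_well(
        self, demo_params, demo_sf
    ):
        """A per-dose parameter can only improve on a shared one when the
        generating truth really differs between doses."""
        times = (0.0, 60.0, 180.0, 360.0, 720.0)
        low = generate_dataset(
            demo_params.replace(k_act=2e-3), demo_sf, doses=(10.0,),
            times=times, noise=NoiseSpec(seed=21), full_panel_doses=(),
        )
        high = generate_dataset(
            demo_params, demo_sf, doses=(100.0,),
            times=times, noise=NoiseSpec(seed=22), full_panel_doses=(),
        )
        merged = Dataset(
            pd.concat([low.dataset.frame, high.dataset.frame], ignore_index=True),
            provenance="synthetic",
        )
        wb = [
            ParamSpec("WB_STAT1D", 1e-3, 1e6, scope="local"),
            ParamSpec("WB_STAT1", 1e-3, 1e6, scope="local"),
        ]
        settings = OptimizerSettings(
            n_restarts=1, sa_iterations=60, local_max_iterations=30, seed=9
        )
        chi2 = {}
        for scope in ("global", "local"):
            space = ParameterSpace(
                [ParamSpec("k_act", 1e-5, 1e-2, scope=scope)] + wb,
                base=demo_params,
            )
            chi2[scope] = fit(merged, space, settings).chi2
        assert chi2["local"] <= chi2["global"] + 1e-9
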