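import numpy as np
import pytest

from enzopt.campaign import (
    CampaignConfig,
    check_convergence,
    mean_posterior_variance,
    run_campaign,
)
from enzopt.design_space import DesignSpace, ParameterSpec
from enzopt.landscapes import NoiseModel
from enzopt.optimizers import AlgorithmVariant, BOConfig
from enzopt.optimizers.base import point_key
from enzopt.optimizers.gp import fit_gp


class TestConvergenceRule:
    def test_slow_trace_converges(self):
        trace = [100, 101, 102, 103, 104, 104.9]
        assert check_convergence(trace, window=5, threshold=0.05)

    def test_exact_threshold_does_not_converge(self):
        trace = [100, 101, 102, 103, 104, 105.0]
        assert not check_convergence(trace, window=5, threshold=0.05)

    def test_doubling_trace_never_converges(self):
        trace = [1.0]
        for _ in range(20):
            trace.append(trace[-1] * 2)
            assert not check_convergence(trace, window=5, threshold=0.05)

    def test_short_trace_never_converges(self):
        assert not check_convergence([1, 1, 1], window=5, threshold=0.05)

    def test_zero_reference(self):
        assert check_convergence([0, 0, 0, 0, 0, 0], 5, 0.05)
        assert not check_convergence([0, 0, 0, 0, 0, 1.0], 5, 0.05)

    def test_negative_trace_rejected(self):
        with pytest.raises(ValueError):
            check_convergence([-1, 2], 5, 0.05)


class TestRunCampaign:
    def test_rs_noiseless_best_trace_is_running_max(
        self, coarse_space, synthetic_coarse
    ):
        res = run_campaign(
            AlgorithmVariant("rs"),
            synthetic_coarse,
            NoiseModel(cv=0.0),
            coarse_space,
            CampaignConfig(max_iterations=6, stop_on_convergence=False, seed=4),
        )
        all_vals = []
        for i, (_, vals) in enumerate(res.iterations):
            all_vals.extend(vals)
            assert res.best_trace[i] == pytest.approx(max(all_vals))
        assert res.best_trace == sorted(res.best_trace)

    def test_target_reached_in_initial_batch(self, coarse_space, synthetic_coarse):
        res = run_campaign(
            AlgorithmVariant("rs"),
            synthetic_coarse,
            NoiseModel(cv=0.0),
            coarse_space,
            CampaignConfig(max_iterations=10, y_target=0.001, seed=0),
        )
        assert res.iterations_run == 1
        assert res.reason == "target"

    def test_experiment_count_conservation(self, coarse_space, synthetic_coarse):
        res = run_campaign(
            AlgorithmVariant("sa"),
            synthetic_coarse,
            NoiseModel(cv=0.132),
            coarse_space,
            CampaignConfig(max_iterations=5, stop_on_convergence=False, seed=1),
        )
        assert res.experiment_count == sum(len(v) for _, v in res.iterations)
        assert res.experiment_count == 8 * res.iterations_run

    def test_no_duplicate_points_across_iterations(
        self, coarse_space, synthetic_coarse
    ):
        for algo in ("rs", "ga", "pso", "sa"):
            res = run_campaign(
                AlgorithmVariant(algo),
                synthetic_coarse,
                NoiseModel(cv=0.132),
                coarse_space,
                CampaignConfig(max_iterations=5, stop_on_convergence=False, seed=2),
            )
            keys = [point_key(p) for pts, _ in res.iterations for p in pts]
            assert len(keys) == len(set(keys)), algo

    def test_reproducibility_bit_identical(self, coarse_space, synthetic_coarse):
        cfg = CampaignConfig(max_iterations=4, stop_on_convergence=False, seed=7)
        a = run_campaign(
            AlgorithmVariant("ga"),
            synthetic_coarse,
            NoiseModel(cv=0.132),
            coarse_space,
            cfg,
        )
        b = run_campaign(
            AlgorithmVariant("ga"),
            synthetic_coarse,
            NoiseModel(cv=0.132),
            coarse_space,
            cfg,
        )
        assert a.to_json() == b.to_json()

    def test_shared_initial_batch_used_verbatim(self, coarse_space, synthetic_coarse):
        batch = [coarse_space.point_from_index(i) for i in (0, 5, 100, 2000)]
        res = run_campaign(
            AlgorithmVariant("rs"),
            synthetic_coarse,
            NoiseModel(cv=0.0),
            coarse_space,
            CampaignConfig(batch_size=4, max_iterations=2, stop_on_convergence=False, seed=0),
            initial_batch=batch,
        )
        got = res.iterations[0][0]
        assert all(np.array_equal(x, y) for x, y in zip(batch, got))

    def test_convergence_stop_reports_reason(self, coarse_space):
        from enzopt.landscapes import Landscape

        flat = Landscape(lambda p: 50.0, coarse_space)
        res = run_campaign(
            AlgorithmVariant("rs"),
            flat,
            NoiseModel(cv=0.0),
            coarse_space,
            CampaignConfig(max_iterations=20, stop_on_convergence=True, seed=0),
        )
        assert res.converged and res.reason == "converged"
        # flat trace converges at the earliest possible length: window + 1
        assert res.iterations_run == 6

    def test_rsm_campaign_spends_150_experiments(
        self, coarse_space, synthetic_coarse
    ):
        res = run_campaign(
            AlgorithmVariant("rsm"),
            synthetic_coarse,
            NoiseModel(cv=0.132),
            coarse_space,
            CampaignConfig(max_iterations=10, stop_on_convergence=False, seed=3),
        )
        assert res.experiment_count == 150
        assert res.iterations_run == 3
        assert res.reason == "exhausted"

    def test_exhaustion_on_tiny_grid(self):
        space = DesignSpace([ParameterSpec("x", 0.0, 1.0, 0.25)])
        from enzopt.landscapes import Landscape

        land = Landscape(lambda p: float(p[0]), space)
        res = run_campaign(
            AlgorithmVariant("rs"),
            land,
            NoiseModel(cv=0.0),
            space,
            CampaignConfig(
                batch_size=2, max_iterations=10, stop_on_convergence=False, seed=0
            ),
        )
        assert res.reason == "exhausted"
        assert res.experiment_count == 5

    def test_best_after_experiments(self, coarse_space, synthetic_coarse):
        res = run_campaign(
            AlgorithmVariant("rs"),
            synthetic_coarse,
            NoiseModel(cv=0.0),
            coarse_space,
            CampaignConfig(max_iterations=4, stop_on_convergence=False, seed=5),
        )
        first_batch_vals = res.iterations[0][1]
        assert res.best_after_experiments(8) == pytest.approx(max(first_batch_vals))
        assert res.best_after_experiments(32) == pytest.approx(res.best_value)


class TestPosteriorVariance:
    def test_prior_variance_without_informative_data(self, coarse_space):
        cfg = BOConfig(noise_variance=0.02)
        hist = [(coarse_space.point_from_index(0), 5.0)]
        model = fit_gp(hist, coarse_space, cfg, length_scale=0.01)
        mpv = mean_posterior_variance(model, coarse_space, n_probe=200, seed=0)
        assert mpv == pytest.approx(1.0, rel=0.02)

    def test_saturation_approaches_noise_floor(self):
        """Densely observed grid: mean posterior variance falls into the
        noise band (0.01–0.0225) that signals model uncertainty = noise."""
        space = DesignSpace([ParameterSpec("x", 0.0, 1.0, 0.1)])
        cfg = BOConfig(noise_variance=0.02)
        hist = [
            (np.array([x]), float(np.sin(x))) for x in np.arange(0, 1.001, 0.1)
        ]
        model = fit_gp(hist, space, cfg, length_scale=0.05)
        mpv = mean_posterior_variance(model, space, n_probe=11, seed=0)
        assert 0.01 <= mpv <= 0.0225

    def test_variance_decreases_with_more_data(self, coarse_space):
        cfg = BOConfig(noise_variance=0.02)
        rng = np.random.default_rng(0)
        idx = rng.choice(coarse_space.grid_cardinality(), 60, replace=False)
        pts = [coarse_space.point_from_index(int(i)) for i in idx]
        vals = rng.uniform(0, 1, 60)
        hist = list(zip(pts, vals))
        m_small = fit_gp(hist[:10], coarse_space, cfg, length_scale=0.5)
        m_large = fit_gp(hist, coarse_space, cfg, length_scale=0.5)
        v_small = mean_posterior_variance(m_small, coarse_space, 300, seed=1)
        v_large = mean_posterior_variance(m_large, coarse_space, 300, seed=1)
        assert v_large < v_small

    def test_bo_campaign_tracks_posterior_variance(
        self, coarse_space, synthetic_coarse
    ):
        res = run_campaign(
            AlgorithmVariant("bo", BOConfig()),
            synthetic_coarse,
            NoiseModel(cv=0.132),
            coarse_space,
            CampaignConfig(max_iterations=3, stop_on_convergence=False, seed=0),
            track_posterior_variance=True,
        )
        assert len(res.posterior_variance_trace) == 2  # fits happen from iter 1
        assert all(v >= 0 for v in res.posterior_variance_trace)
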