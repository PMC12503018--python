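import math

import numpy as np
import pytest

from enzopt.design_space import Bounds, DesignSpace, ParameterSpec, full_factorial_3
from enzopt.optimizers import (
    AlgorithmVariant,
    BOConfig,
    GAConfig,
    PSOConfig,
    SAConfig,
    make_optimizer,
    propose_batch_bo,
    rank_selection_probabilities,
)
from enzopt.optimizers.base import RSOptimizer, point_key
from enzopt.optimizers.bo import BOOptimizer
from enzopt.optimizers.evolutionary import GAOptimizer, PSOOptimizer, SAOptimizer
from enzopt.optimizers.gp import fit_gp, matern_covariance, acquisition
from enzopt.optimizers.rsm import (
    RSMOptimizer,
    fit_quadratic_model,
    rsm_design_round,
    rsm_next_region,
)


def _grid1d(n_levels=5):
    return DesignSpace([ParameterSpec("x", 0.0, 1.0, 1.0 / (n_levels - 1))])


def _tell_initial(opt, space, seed=0, values=None):
    """Feed a first evaluated batch into an optimizer."""
    rng = np.random.default_rng(seed)
    card = space.grid_cardinality()
    idx = rng.choice(card, size=opt.batch_size, replace=False)
    pts = [space.point_from_index(int(i)) for i in idx]
    if values is None:
        values = rng.uniform(1, 100, size=len(pts)).tolist()
    opt.tell(pts, values)
    return pts, values


class TestBatchBO:
    def test_q1_is_acquisition_argmax(self):
        space = _grid1d(5)
        config = BOConfig(kernel="matern32")
        history = [(np.array([0.0]), 1.0), (np.array([1.0]), 2.0)]
        model = fit_gp(history, space, config, length_scale=0.3)
        batch, exhausted = propose_batch_bo(
            history, space, config, q=1, seed=0, model=model
        )
        assert len(batch) == 1 and not exhausted
        cands = np.array([[0.25], [0.5], [0.75]])
        mean, var = model.predict(cands)
        acq = acquisition(mean, np.sqrt(var), model.best_scaled, config)
        assert batch[0][0] == pytest.approx(cands[np.argmax(acq)][0])

    def test_hand_traced_kriging_believer_on_5_point_grid(self):
        """Batch order must match an independent believer trace built from
        the closed-form GP posterior."""
        space = _grid1d(5)
        config = BOConfig(kernel="matern32", noise_variance=0.02, xi=0.01)
        history = [(np.array([0.0]), 10.0), (np.array([1.0]), 20.0)]
        ls = 0.4
        model = fit_gp(history, space, config, length_scale=ls)
        batch, _ = propose_batch_bo(history, space, config, q=3, seed=0, model=model)

        # oracle on the scaled problem (y: 10 -> 0, 20 -> 1)
        def k(a, b):
            return matern_covariance(abs(a - b), ls, 1.5)

        xs_train = [0.0, 1.0]
        ys_train = [0.0, 1.0]
        best = 1.0
        chosen = []
        candidates = [0.25, 0.5, 0.75]
        from scipy.stats import norm

        for _ in range(3):
            K = np.array([[k(a, b) for b in xs_train] for a in xs_train])
            K += 0.02 * np.eye(len(xs_train))
            Kinv = np.linalg.inv(K)
            scores, means = [], []
            for c in candidates:
                ks = np.array([k(c, b) for b in xs_train])
                m = ks @ Kinv @ np.array(ys_train)
                v = max(k(0, 0) - ks @ Kinv @ ks, 0.0)
                s = math.sqrt(v)
                imp = m - best - 0.01
                z = imp / s if s > 0 else 0.0
                ei = imp * norm.cdf(z) + s * norm.pdf(z) if s > 0 else max(imp, 0)
                scores.append(ei)
                means.append(m)
            pick = int(np.argmax(scores))
            chosen.append(candidates[pick])
            xs_train.append(candidates[pick])
            ys_train.append(means[pick])
            best = max(ys_train)
            candidates.pop(pick)
        assert [round(b[0], 6) for b in batch] == [round(c, 6) for c in chosen]

    def test_q8_unique_and_disjoint_from_history(self, coarse_space):
        opt = BOOptimizer(coarse_space, batch_size=8, config=BOConfig())
        pts, _ = _tell_initial(opt, coarse_space, seed=1)
        batch = opt.propose(np.random.default_rng(2))
        assert len(batch) == 8
        keys = {point_key(p) for p in batch}
        assert len(keys) == 8
        assert keys.isdisjoint({point_key(p) for p in pts})

    def test_exhaustion_flagged(self):
        space = _grid1d(5)
        history = [(np.array([x]), float(x)) for x in (0.0, 0.25, 0.5)]
        batch, exhausted = propose_batch_bo(
            history, space, BOConfig(), q=8, seed=0,
            model=fit_gp(history, space, BOConfig(), length_scale=0.3),
        )
        assert exhausted and len(batch) == 2


class TestGA:
    def test_rank_selection_probabilities(self):
        p = rank_selection_probabilities(8)
        assert p[-1] == pytest.approx(8 / 36)
        assert p[0] == pytest.approx(1 / 36)
        assert p.sum() == pytest.approx(1.0)

    def test_zero_mutation_identical_parents_clone(self, coarse_space):
        cfg = GAConfig(elitism=2, mutation_probability=0.0)
        opt = GAOptimizer(coarse_space, batch_size=8, config=cfg)
        opt.enforce_no_repeat = False  # isolate the variation operators
        pt = coarse_space.point_from_index(1234)
        opt.tell([pt] * 8, list(range(8)))
        batch = opt.propose(np.random.default_rng(0))
        assert len(batch) == 6  # 8 minus 2 elites
        for child in batch:
            assert np.array_equal(child, pt)

    def test_elites_not_respent_and_kept_in_population(self, coarse_space):
        cfg = GAConfig(elitism=2, mutation_probability=0.4)
        opt = GAOptimizer(coarse_space, batch_size=8, config=cfg)
        pts, values = _tell_initial(opt, coarse_space, seed=3)
        best2 = {point_key(pts[i]) for i in np.argsort(values)[-2:]}
        batch = opt.propose(np.random.default_rng(1))
        assert len(batch) == 6
        opt.tell(batch, list(np.random.default_rng(2).uniform(0, 50, 6)))
        pop_keys = {point_key(p) for p in opt.population}
        assert best2 <= pop_keys

    def test_batch_unique_and_disjoint_from_history(self, coarse_space):
        opt = GAOptimizer(coarse_space, batch_size=8, config=GAConfig())
        pts, _ = _tell_initial(opt, coarse_space, seed=5)
        batch = opt.propose(np.random.default_rng(7))
        keys = {point_key(p) for p in batch}
        assert len(keys) == len(batch)
        assert keys.isdisjoint({point_key(p) for p in pts})

    def test_default_config_is_best_screened_variant(self):
        cfg = GAConfig()
        assert (cfg.elitism, cfg.mutation_probability, cfg.mutation_extent) == (
            2,
            0.4,
            0.3,
        )
        assert (cfg.crossover, cfg.selection) == ("random", "rank")


class _OnesRng:
    """Stub generator: uniform() -> 1, used to hand-check update rules."""

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.ones(size) if size is not None else 1.0

    def random(self, size=None):
        return np.zeros(size) if size is not None else 0.0

    def integers(self, *a, **k):
        return 0


class TestPSO:
    def test_stationary_at_consensus(self, coarse_space):
        opt = PSOOptimizer(coarse_space, batch_size=2)
        opt.enforce_no_repeat = False
        pt = coarse_space.point_from_index(999)
        opt.tell([pt, pt], [5.0, 5.0])
        batch = opt.propose(np.random.default_rng(0))
        for p in batch:
            assert np.array_equal(p, pt)

    def test_velocity_update_rule_hand_computed(self):
        # 1-D: w=0.9, c1=2.5, c2=1.0, r1=r2=1, v=0, x=0, pbest=1, gbest=2
        space = DesignSpace([ParameterSpec("x", 0.0, 10.0, 0.5)])
        cfg = PSOConfig(w0=0.9, cd=0.95, c1=2.5, c2=1.0)
        opt = PSOOptimizer(space, batch_size=1, config=cfg)
        opt.enforce_no_repeat = False
        opt.tell([np.array([0.0])], [1.0])
        opt.pbest_x = np.array([[1.0]])
        opt.pbest_y = np.array([2.0])
        opt.gbest_x = np.array([2.0])
        opt.gbest_y = 3.0
        batch = opt.propose(_OnesRng())
        # v = 0.9*0 + 2.5*1*(1-0) + 1.0*1*(2-0) = 4.5 -> x = 4.5
        assert opt.v[0, 0] == pytest.approx(4.5)
        assert batch[0][0] == pytest.approx(4.5)

    def test_inertia_decays(self, coarse_space):
        cfg = PSOConfig(w0=0.9, cd=0.95)
        opt = PSOOptimizer(coarse_space, batch_size=4, config=cfg)
        _tell_initial(opt, coarse_space, seed=1)
        opt.propose(np.random.default_rng(0))
        assert opt.w == pytest.approx(0.9 * 0.95)

    def test_batch_disjoint_from_history(self, coarse_space):
        opt = PSOOptimizer(coarse_space, batch_size=8)
        pts, _ = _tell_initial(opt, coarse_space, seed=2)
        batch = opt.propose(np.random.default_rng(3))
        keys = {point_key(p) for p in batch}
        assert len(keys) == len(batch)
        assert keys.isdisjoint({point_key(p) for p in pts})

    def test_default_config_is_best_screened_variant(self):
        cfg = PSOConfig()
        assert (cfg.w0, cfg.cd, cfg.c1, cfg.c2) == (0.9, 0.95, 2.5, 1.0)


class TestSA:
    def test_improvement_always_accepted(self, coarse_space):
        opt = SAOptimizer(coarse_space, batch_size=2)
        pts, _ = _tell_initial(opt, coarse_space, seed=0, values=[10.0, 10.0])
        batch = opt.propose(np.random.default_rng(1))
        opt.tell(batch, [100.0, 100.0])
        for x, y in zip(opt.current_x, opt.current_y):
            assert y == 100.0

    def test_acceptance_frequency_matches_boltzmann(self, coarse_space):
        """At Δ = −T the worse-move acceptance rate must be e^-1 (within 3
        standard errors over 10^4 trials)."""
        cfg = SAConfig(T0=100.0, cT=0.5, S0=0.8)
        n = 10_000
        rng = np.random.default_rng(42)
        accepted = 0
        opt = SAOptimizer(coarse_space, batch_size=1, config=cfg)
        opt._accept_rng = rng
        opt.current_x = [np.zeros(5)]
        for _ in range(n):
            opt.current_y = [500.0]
            opt.k = 0  # T = 100
            opt._update([np.ones(5)], [400.0])  # Δ = −100 = −T
            if opt.current_y[0] == 400.0:
                accepted += 1
            opt.k = 0
        p = math.exp(-1)
        se = math.sqrt(p * (1 - p) / n)
        assert accepted / n == pytest.approx(p, abs=3 * se)

    def test_geometric_cooling(self, coarse_space):
        cfg = SAConfig(T0=380.0, cT=0.7, S0=0.8)
        opt = SAOptimizer(coarse_space, batch_size=2, config=cfg)
        _tell_initial(opt, coarse_space, seed=3)
        assert opt.temperature == pytest.approx(380.0)
        b = opt.propose(np.random.default_rng(0))
        opt.tell(b, [1.0] * len(b))
        assert opt.temperature == pytest.approx(380.0 * 0.7)

    def test_default_config_is_best_screened_variant(self):
        cfg = SAConfig()
        assert (cfg.T0, cfg.cT, cfg.S0) == (380.0, 0.7, 0.8)

    def test_batch_disjoint_from_history(self, coarse_space):
        opt = SAOptimizer(coarse_space, batch_size=8)
        pts, _ = _tell_initial(opt, coarse_space, seed=9)
        batch = opt.propose(np.random.default_rng(4))
        keys = {point_key(p) for p in batch}
        assert len(keys) == len(batch)
        assert keys.isdisjoint({point_key(p) for p in pts})


class TestRS:
    def test_returns_only_remaining_point(self):
        space = DesignSpace([ParameterSpec("x", 0.0, 1.0, 0.5)])
        opt = RSOptimizer(space, batch_size=1)
        opt.tell([np.array([0.0]), np.array([0.5])], [1.0, 2.0])
        batch = opt.propose(np.random.default_rng(0))
        assert len(batch) == 1 and batch[0][0] == pytest.approx(1.0)

    def test_seeded_reproducibility(self, coarse_space):
        a = RSOptimizer(coarse_space, batch_size=8)
        b = RSOptimizer(coarse_space, batch_size=8)
        _tell_initial(a, coarse_space, seed=0)
        _tell_initial(b, coarse_space, seed=0)
        ba = a.propose(np.random.default_rng(5))
        bb = b.propose(np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(ba, bb))


class TestRSMDesign:
    def test_50_points_for_d5(self, coarse_space):
        pts = rsm_design_round(coarse_space.bounds())
        assert len(pts) == 50
        b = coarse_space.bounds()
        arr = np.array(pts)
        assert np.all(arr >= b.lower) and np.all(arr <= b.upper)
        n_center = sum(np.allclose(p, b.center) for p in pts)
        assert n_center == 8

    def test_corner_and_axial_structure(self):
        b = Bounds(((0.0, 1.0), (0.0, 2.0)))
        pts = rsm_design_round(b, center_replicates=3)
        assert len(pts) == 4 + 4 + 3


class TestQuadraticModel:
    def _quad(self, x):
        # known quadratic in scaled coordinates
        return 3.0 + 2.0 * x[:, 0] - x[:, 1] + 0.5 * x[:, 0] * x[:, 1] - x[:, 0] ** 2

    def test_exact_recovery_on_noiseless_quadratic(self):
        b = Bounds(((0.0, 1.0), (0.0, 1.0)))
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(30, 2))
        xs = 2.0 * (pts - b.center) / b.widths
        y = self._quad(xs)
        model = fit_quadratic_model(list(zip(pts, y)), b)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.predict(pts), y, atol=1e-8)

    def test_against_statsmodels_ols_oracle(self):
        import statsmodels.api as sm

        b = Bounds(((0.0, 2.0), (1.0, 3.0), (0.0, 1.0)))
        rng = np.random.default_rng(1)
        pts = rng.uniform(b.lower, b.upper, size=(30, 3))
        y = rng.uniform(0, 10, size=30)
        model = fit_quadratic_model(list(zip(pts, y)), b)
        from enzopt.optimizers.rsm import _quadratic_features

        xs = 2.0 * (pts - b.center) / b.widths
        X = _quadratic_features(xs)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(model.predict(pts), ols.predict(X), atol=1e-6)
        assert model.r_squared == pytest.approx(ols.rsquared, abs=1e-8)

    def test_constant_response_degenerate_r2(self):
        b = Bounds(((0.0, 1.0),))
        pts = np.linspace(0, 1, 10)[:, None]
        model = fit_quadratic_model([(p, 4.0) for p in pts], b)
        assert model.r_squared == 1.0
        assert model.degenerate_variance

    def test_rank_deficiency_flagged(self):
        b = Bounds(((0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)))
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(10, 5))  # fewer than 21 coefficients
        y = rng.uniform(0, 1, size=10)
        model = fit_quadratic_model(list(zip(pts, y)), b)
        assert model.rank_deficient


class TestRSMNextRegion:
    def test_interior_peak_found(self):
        b = Bounds(((0.0, 1.0), (0.0, 1.0)))
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(40, 2))
        y = -((pts[:, 0] - 0.6) ** 2) - (pts[:, 1] - 0.4) ** 2
        model = fit_quadratic_model(list(zip(pts, y)), b)
        opt, nb = rsm_next_region(model, b, b, scan_levels=41)
        assert opt[0] == pytest.approx(0.6, abs=0.03)
        assert opt[1] == pytest.approx(0.4, abs=0.03)
        assert nb.widths[0] == pytest.approx(0.5)

    def test_corner_maximum_hugs_corner(self):
        b = Bounds(((0.0, 1.0),))
        pts = np.linspace(0, 1, 25)[:, None]
        y = pts[:, 0]  # maximized at the upper corner
        model = fit_quadratic_model(list(zip(pts, y)), b)
        opt, nb = rsm_next_region(model, b, b, scan_levels=21)
        assert opt[0] == pytest.approx(1.0)
        assert nb.pairs == ((0.5, 1.0),)


class TestVariantFactory:
    def test_all_algorithms_constructible(self, coarse_space):
        for algo in ("bo", "ga", "pso", "sa", "rs", "rsm"):
            opt = make_optimizer(AlgorithmVariant(algo), coarse_space)
            assert opt.space is coarse_space

    def test_config_type_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AlgorithmVariant("ga", BOConfig())

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            AlgorithmVariant("cmaes")
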