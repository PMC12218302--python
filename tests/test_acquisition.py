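import numpy as np
import pytest

from mediabo.acquisition import (
    AcquisitionConfig,
    BanditState,
    bandit_select_category,
    constant_liar_batch,
    maximize_acquisition,
    suggest_batch,
    thompson_batch,
    ucb,
)
from mediabo.design_space import DesignFactor, DesignSpace
from mediabo.gp_model import TrainingSet, fit_gp


def fit_1d(rng, n=8, bumpy=True):
    x = np.linspace(0.05, 0.95, n)[:, None]
    y = np.sin(6 * x[:, 0]) if bumpy else x[:, 0]
    train = TrainingSet(x, np.zeros((n, 0), dtype=int), y, np.full(n, 1e-4))
    return fit_gp(train, n_restarts=3, seed=0)


def space_1d():
    return DesignSpace([DesignFactor(name="x", kind="continuous", lower=0.0, upper=1.0)])


class TestConfig:
    def test_defaults_echo(self):
        cfg = AcquisitionConfig()
        assert cfg.screen_size == 10_000
        assert cfg.kappa == 2.0
        assert cfg.lie == "mean"

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(kind="ei")
        with pytest.raises(ValueError):
            AcquisitionConfig(batch_size=0)
        with pytest.raises(ValueError):
            AcquisitionConfig(screen_size=2, batch_size=6)


class TestUCB:
    def test_arithmetic_and_degenerate_cases(self, rng):
        model = fit_1d(rng)
        x = model.training.x[:1]
        mean, sd = model.predict(x, None)
        assert ucb(model, x, None, 0.0)[0] == pytest.approx(mean[0])
        assert ucb(model, x, None, 2.0)[0] == pytest.approx(mean[0] + 2 * sd[0])

    def test_negative_kappa_rejected(self, rng):
        with pytest.raises(ValueError):
            ucb(fit_1d(rng), np.array([[0.5]]), None, -1.0)


class TestMaximize:
    def test_matches_dense_grid_argmax(self, rng):
        model = fit_1d(rng)
        cfg = AcquisitionConfig(kind="ucb", kappa=2.0, n_restarts=8)
        point = maximize_acquisition(model, cfg, space_1d(), seed=0)
        grid = np.linspace(0, 1, 10_001)[:, None]
        scores = ucb(model, grid, None, 2.0)
        best = grid[int(np.argmax(scores)), 0]
        got = float(point["x"])
        got_score = ucb(model, np.array([[got]]), None, 2.0)[0]
        assert abs(got - best) < 1e-3 or got_score >= scores.max() - 1e-9

    def test_simplex_suggestion_feasible(self, rng, blend_space):
        n = 10
        x = np.random.default_rng(0).dirichlet(np.ones(4), size=n)
        y = x[:, 0] * 0.5 + x[:, 1]  # prefer AR5
        train = TrainingSet(x, np.zeros((n, 0), dtype=int), y, np.full(n, 1e-4))
        model = fit_gp(train, n_restarts=2, seed=0)
        point = maximize_acquisition(model, AcquisitionConfig(n_restarts=3), blend_space, seed=1)
        assert abs(sum(float(v) for v in point.values.values()) - 1.0) <= 1e-6
        assert blend_space.validate_point(point).valid

    def test_brute_force_screen_deterministic(self, rng, tiny_mixed_space):
        gen = np.random.default_rng(1)
        x = gen.uniform(size=(12, 2))
        h = gen.integers(0, 3, size=(12, 1))
        train = TrainingSet(x, h, gen.uniform(size=12), np.full(12, 1e-3))
        model = fit_gp(train, n_categories=(3,), n_restarts=2, seed=0)
        cfg = AcquisitionConfig(kind="brute_force_screen", screen_size=500)
        a = maximize_acquisition(model, cfg, tiny_mixed_space, seed=7)
        b = maximize_acquisition(model, cfg, tiny_mixed_space, seed=7)
        assert a.values == b.values


class TestBandit:
    def test_single_arm_always_selected(self, rng):
        state = BanditState(1)
        assert all(bandit_select_category(state, rng) == 0 for _ in range(10))

    def test_uniform_without_history(self, rng):
        state = BanditState(4)
        draws = [bandit_select_category(state, rng) for _ in range(10_000)]
        freq = np.bincount(draws, minlength=4) / len(draws)
        assert np.allclose(freq, 0.25, atol=0.02)

    def test_rewarded_arm_dominates(self, rng):
        state = BanditState(4)
        for _ in range(50):
            state.update(2, 1.0)
            for arm in (0, 1, 3):
                state.update(arm, 0.0)
        assert state.probabilities()[2] > 0.5

    def test_no_arm_starved(self, rng):
        state = BanditState(3)
        for _ in range(200):
            state.update(0, 1.0)
        assert np.all(state.probabilities() > 0)


class TestThompson:
    def test_dominant_candidate_selected(self, rng):
        # dense noise-free training: posterior sd ~ 0 everywhere, so every
        # sample path peaks at the known bump
        n = 60
        x = np.linspace(0, 1, n)[:, None]
        y = np.exp(-((x[:, 0] - 0.72) ** 2) / 0.02)
        train = TrainingSet(x, np.zeros((n, 0), dtype=int), y, np.full(n, 1e-6))
        model = fit_gp(train, n_restarts=2, seed=0)
        hits = 0
        n_draws = 100
        for i in range(n_draws):
            pts = thompson_batch(model, space_1d(), 1, 128, seed=i)
            if abs(float(pts[0]["x"]) - 0.72) < 0.1:
                hits += 1
        assert hits > 0.95 * n_draws

    def test_batch_reproducible_and_distinct(self, rng):
        model = fit_1d(rng)
        a = thompson_batch(model, space_1d(), 3, 64, seed=5)
        b = thompson_batch(model, space_1d(), 3, 64, seed=5)
        assert [p.values for p in a] == [p.values for p in b]
        xs = {round(float(p["x"]), 9) for p in a}
        assert len(xs) == 3


class TestConstantLiar:
    def test_batch_of_one_equals_single_maximization(self, rng):
        model = fit_1d(rng)
        cfg = AcquisitionConfig(kind="ucb", batch_size=1, n_restarts=4)
        rs = np.random.default_rng(3)
        batch = constant_liar_batch(model, cfg, space_1d(), seed=3)
        single = maximize_acquisition(model, cfg, space_1d(), int(rs.integers(2**31)))
        assert batch[0].values == single.values

    def test_six_distinct_points(self, rng):
        model = fit_1d(rng)
        cfg = AcquisitionConfig(kind="ucb", batch_size=6, n_restarts=3)
        batch = constant_liar_batch(model, cfg, space_1d(), seed=2)
        xs = np.array([float(p["x"]) for p in batch])
        dists = np.abs(xs[:, None] - xs[None, :])[np.triu_indices(6, 1)]
        assert np.min(dists) > 1e-6

    def test_lie_reduces_acquisition_at_lied_point(self, rng):
        model = fit_1d(rng)
        cfg = AcquisitionConfig(kind="ucb", batch_size=1, n_restarts=4)
        point = constant_liar_batch(model, cfg, space_1d(), seed=1)[0]
        x = np.array([[float(point["x"])]])
        before = ucb(model, x, None, cfg.kappa)[0]
        lied = model.with_observation(x, np.zeros((1, 0), dtype=int),
                                      float(np.mean(model.training.y)))
        after = ucb(lied, x, None, cfg.kappa)[0]
        assert after < before

    def test_original_model_untouched(self, rng):
        model = fit_1d(rng)
        n_before = model.training.n
        constant_liar_batch(model, AcquisitionConfig(batch_size=3, n_restarts=2),
                            space_1d(), seed=0)
        assert model.training.n == n_before


class TestSuggestDispatch:
    def test_kappa_increases_exploration_distance(self, rng):
        model = fit_1d(rng, n=6, bumpy=False)
        dists = []
        for kappa in (0.0, 20.0):
            cfg = AcquisitionConfig(kind="ucb", kappa=kappa, batch_size=4, n_restarts=4)
            batch = constant_liar_batch(model, cfg, space_1d(), seed=4)
            xs = np.array([float(p["x"]) for p in batch])
            d = [np.min(np.abs(model.training.x[:, 0] - v)) for v in xs]
            dists.append(np.mean(d))
        assert dists[1] > dists[0]

    def test_schedule_override_avoids_bandit(self, rng, tiny_mixed_space):
        gen = np.random.default_rng(2)
        x = gen.uniform(size=(10, 2))
        h = gen.integers(0, 3, size=(10, 1))
        train = TrainingSet(x, h, gen.uniform(size=10), np.full(10, 1e-3))
        model = fit_gp(train, n_categories=(3,), n_restarts=2, seed=0)
        cfg = AcquisitionConfig(batch_size=2, screen_size=200,
                                phase_schedule={1: "brute_force_screen"})
        bandit = BanditState(3)
        w_before = bandit.weights.copy()
        batch = suggest_batch(model, tiny_mixed_space, cfg, iteration=1, seed=0,
                              bandit_state=bandit)
        assert len(batch) == 2
        assert np.array_equal(bandit.weights, w_before) and bandit.t == 0

    def test_mixed_space_suggestions_valid(self, rng, tiny_mixed_space):
        gen = np.random.default_rng(4)
        x = gen.uniform(size=(12, 2))
        h = gen.integers(0, 3, size=(12, 1))
        train = TrainingSet(x, h, gen.uniform(size=12), np.full(12, 1e-3))
        model = fit_gp(train, n_categories=(3,), n_restarts=2, seed=0)
        cfg = AcquisitionConfig(batch_size=3, thompson_screen_size=64, screen_size=200)
        for iteration in (1, 5):  # bandit+Thompson phase, then brute-force phase
            batch = suggest_batch(model, tiny_mixed_space, cfg, iteration, seed=1,
                                  bandit_state=BanditState(3))
            assert len(batch) == 3
            assert all(tiny_mixed_space.validate_point(p).valid for p in batch)
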