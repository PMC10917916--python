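"""Q-GNDO operators (against hand-computed values), search behavior and the
wrapper fitness."""

import numpy as np
import pytest

from mammofuse.selection import (
    Candidate, Population, QuantumState, binarize, fitness,
    global_exploration, init_population, local_exploitation, penalty_factor,
    qgndo_minimize, quantum_update, select_features,
)


def scalar_population(positions, fitnesses, bounds=(-10.0, 10.0)):
    cands = [Candidate(np.array([p]), f)
             for p, f in zip(positions, fitnesses)]
    return Population(cands, bounds=bounds)


class TestPenaltyFactor:
    def test_log_one_is_zero(self):
        assert penalty_factor(1.0, 0.37, 5, 1) == 0.0

    def test_closed_form(self):
        # -ln(e^-1) * cos(0) = 1
        assert penalty_factor(np.exp(-1.0), 0.0, 0, 1) == pytest.approx(1.0)

    def test_branches_are_negations(self):
        a = penalty_factor(0.3, 0.2, 0, 1)   # x <= y
        b = penalty_factor(0.3, 0.2, 2, 1)   # x > y
        assert a == pytest.approx(-b)

    def test_zero_gamma1_rejected(self):
        with pytest.raises(ValueError):
            penalty_factor(0.0, 0.5, 0, 1)


class TestLocalExploitation:
    def test_collapsed_population_is_fixed_point(self):
        pop = scalar_population([2.0, 2.0, 2.0, 2.0], [1.0, 0.5, 0.7, 0.9])
        trial = local_exploitation(pop, 0, np.random.default_rng(0))
        assert trial.position == pytest.approx(np.array([2.0]))

    def test_hand_computed_scalar_case(self, stub_rng):
        """V_j=1, V_best=3, K=2 with CT=0.5: mean 2, std sqrt(2/3),
        trial 2 + sqrt(2/3)*0.5 ~ 2.408 (verified by hand)."""
        # population mean K = mean(1, 3, 2) = 2
        pop = scalar_population([1.0, 3.0, 2.0], [1.0, 0.0, 0.5])
        # CT = -ln(e^-0.5)*cos(0) = 0.5; draws: gamma1, gamma2, x, y
        rng = stub_rng(uniforms=[np.exp(-0.5), 0.0, 0.3, 0.7])
        trial = local_exploitation(pop, 0, rng)
        assert trial.position[0] == pytest.approx(2.0 + np.sqrt(2.0 / 3.0) * 0.5)

    def test_zero_penalty_returns_generalized_mean(self, stub_rng):
        pop = scalar_population([1.0, 3.0, 2.0], [1.0, 0.0, 0.5])
        rng = stub_rng(uniforms=[1.0, 0.42, 0.1, 0.9])  # gamma1=1 -> CT=0
        trial = local_exploitation(pop, 0, rng)
        assert trial.position[0] == pytest.approx(2.0)


class TestGlobalExploration:
    def test_zero_normals_leave_position_unchanged(self, stub_rng):
        pop = scalar_population([1.0, 5.0, -2.0, 3.0], [0.4, 0.1, 0.9, 0.2])
        rng = stub_rng(uniforms=[0.7], normals=[0.0, 0.0],
                       choices=[[1, 2, 3]])
        trial = global_exploration(pop, 0, rng)
        assert trial.position[0] == pytest.approx(1.0)

    def test_screening_direction_points_from_worse_to_better(self, stub_rng):
        # f(V_0)=0.1 < f(V_1)=0.9 -> v1 = V_0 - V_1 = 1 - 5 = -4
        pop = scalar_population([1.0, 5.0, -2.0, 3.0], [0.1, 0.9, 0.5, 0.5])
        rng = stub_rng(uniforms=[1.0], normals=[1.0, 0.0],
                       choices=[[1, 2, 3]])
        trial = global_exploration(pop, 0, rng)
        # Z = V_0 + rho*|g3|*v1 + 0 = 1 + 1*1*(-4) = -3
        assert trial.position[0] == pytest.approx(-3.0)

    def test_drawn_indices_are_distinct_and_exclude_j(self):
        pop = scalar_population([0.0] * 6, [0.1] * 6)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            others = [i for i in range(6) if i != 2]
            l = rng.choice(others, size=3, replace=False)
            assert len(set(l)) == 3 and 2 not in l

    def test_small_population_rejected(self):
        pop = scalar_population([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            global_exploration(pop, 0, np.random.default_rng(0))


class TestQuantumUpdate:
    def _state(self):
        return QuantumState(pbest=np.array([[1.0], [3.0]]),
                            pbest_fitness=np.array([0.5, 0.1]),
                            gbest=np.array([3.0]), gbest_fitness=0.1)

    def test_candidate_at_mean_best_stays_at_attractor(self, stub_rng):
        state = self._state()  # Gbest_mean = 2
        pop = scalar_population([2.0, 3.0], [0.5, 0.1])
        rng = stub_rng(uniforms=[0.5, 0.37, 0.9])  # theta, u, t
        trial = quantum_update(state, pop, 0, rng, beta=1.0)
        assert trial.position[0] == pytest.approx(2.0)  # omega = 2, step = 0

    def test_u_equal_one_kills_the_jump(self, stub_rng):
        state = self._state()
        pop = scalar_population([0.0, 3.0], [0.5, 0.1])
        rng = stub_rng(uniforms=[0.5, 1.0, 0.2])
        trial = quantum_update(state, pop, 0, rng, beta=1.0)
        assert trial.position[0] == pytest.approx(2.0)  # ln(1/1) = 0

    def test_hand_computed_scalar_case(self, stub_rng):
        """pbest=1, gbest=3, theta=0.5, Gbest_mean=2, V_j=0, beta=1,
        u=e^-1, t=0.3 (plus branch): omega=2, Z = 2 + 1*|2-0|*1 = 4."""
        state = self._state()
        pop = scalar_population([0.0, 3.0], [0.5, 0.1])
        rng = stub_rng(uniforms=[0.5, np.exp(-1.0), 0.3])
        trial = quantum_update(state, pop, 0, rng, beta=1.0)
        assert trial.position[0] == pytest.approx(4.0)


class TestInitPopulation:
    def test_degenerate_box_collapses_to_point(self):
        pop = init_population(5, 3, (0.0, 0.0), 1)
        for c in pop.candidates:
            assert np.array_equal(c.position, np.zeros(3))

    def test_within_bounds_and_deterministic(self):
        a = init_population(6, 4, (-2.0, 3.0), 7)
        b = init_population(6, 4, (-2.0, 3.0), 7)
        for ca, cb in zip(a.candidates, b.candidates):
            assert np.array_equal(ca.position, cb.position)
            assert (ca.position >= -2.0).all() and (ca.position <= 3.0).all()

    def test_too_small_population_rejected(self):
        with pytest.raises(ValueError):
            init_population(3, 2, (0, 1), 0)


class TestPositionsStayInBounds:
    def test_operators_always_clamp(self):
        """Audit over many random updates: every operator's output stays in
        the search box."""
        rng = np.random.default_rng(0)
        pop = init_population(8, 3, (-1.0, 2.0), rng)
        for c in pop.candidates:
            c.fitness = float((c.position ** 2).sum())
        state = QuantumState(
            pbest=np.stack([c.position for c in pop.candidates]),
            pbest_fitness=np.array([c.fitness for c in pop.candidates]),
            gbest=pop.best_candidate.position.copy(),
            gbest_fitness=pop.best_candidate.fitness)
        for _ in range(2000):
            j = int(rng.integers(8))
            for trial in (local_exploitation(pop, j, rng),
                          global_exploration(pop, j, rng),
                          quantum_update(state, pop, j, rng)):
                assert (trial.position >= -1.0).all()
                assert (trial.position <= 2.0).all()


class TestFitness:
    def test_closed_form_costs(self, monkeypatch):
        import mammofuse.classify as classify

        X = np.zeros((10, 100))
        y = np.arange(10) % 2
        monkeypatch.setattr(classify, "crossval_accuracy",
                            lambda *a, **k: 1.0)
        full = np.ones(100, dtype=bool)
        assert fitness(full, X, y) == pytest.approx(0.01)
        monkeypatch.setattr(classify, "crossval_accuracy",
                            lambda *a, **k: 0.0)
        one = np.zeros(100, dtype=bool)
        one[0] = True
        assert fitness(one, X, y) == pytest.approx(0.9901)

    def test_reported_operating_point(self, monkeypatch):
        """Accuracy 96.5% with 1,572 of 4,096 columns costs ~ 0.0385."""
        import mammofuse.classify as classify
        monkeypatch.setattr(classify, "crossval_accuracy",
                            lambda *a, **k: 0.965)
        mask = np.zeros(4096, dtype=bool)
        mask[:1572] = True
        cost = fitness(mask, np.zeros((4, 4096)), np.array([0, 1, 0, 1]))
        assert cost == pytest.approx(0.99 * 0.035 + 0.01 * 1572 / 4096,
                                     abs=1e-12)

    def test_empty_mask_gets_worst_cost(self):
        assert fitness(np.zeros(10, dtype=bool), np.zeros((4, 10)),
                       np.array([0, 1, 0, 1])) == 1.0


class TestSearch:
    def test_history_is_monotone_nonincreasing(self):
        _, _, hist, _ = qgndo_minimize(
            lambda z: float((z ** 2).sum()), 3, bounds=(-5, 5), n=6,
            iters=20, seed=1)
        assert all(b <= a for a, b in zip(hist, hist[1:]))

    def test_sphere_smoke(self):
        _, cost, _, _ = qgndo_minimize(
            lambda z: float((z ** 2).sum()), 2, bounds=(-10, 10), n=30,
            iters=100, seed=0)
        assert cost < 1e-2

    def test_select_features_deterministic(self, tiny_benchmark):
        cfg = {"preset": "narrow", "max_iter": 20}
        kw = dict(n=4, iters=2, seed=3, classifier_cfg=cfg, folds=2)
        a = select_features(tiny_benchmark.X, tiny_benchmark.y, **kw)
        b = select_features(tiny_benchmark.X, tiny_benchmark.y, **kw)
        assert np.array_equal(a.mask, b.mask)
        assert a.cost == b.cost
        assert a.history == b.history

    def test_zero_iterations_returns_initial_best(self, tiny_benchmark):
        res = select_features(tiny_benchmark.X, tiny_benchmark.y, n=4,
                              iters=0, seed=2,
                              classifier_cfg={"preset": "narrow",
                                              "max_iter": 20}, folds=2)
        assert res.mask.any()
        assert res.cost <= 1.0

    def test_degenerate_labels_rejected(self, tiny_benchmark):
        with pytest.raises(ValueError):
            select_features(tiny_benchmark.X,
                            np.zeros_like(tiny_benchmark.y), n=4, iters=1,
                            seed=0)

    def test_binarize_threshold(self):
        assert np.array_equal(binarize(np.array([0.2, 0.5, 0.8])),
                              np.array([False, False, True]))
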