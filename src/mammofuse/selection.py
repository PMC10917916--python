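"""Quantum-enhanced generalized normal distribution optimization (Q-GNDO)
and its binary wrapper feature selector.

GNDO is a population metaheuristic with two moves:

* *local exploitation* samples around a generalized mean built from the
  candidate, the population best and the population mean,
  ``Z = m + s * CT``, where ``m = (V_j + V_best + K) / 3``, ``s`` is the
  element-wise generalized standard deviation of the three anchors around
  ``m``, and ``CT = -ln(g1) * cos(2*pi*g2 [+ pi])`` is a signed penalty
  factor;
* *global exploration* mixes fitness-screened differences of three distinct
  random individuals,
  ``Z = V_j + rho*|g3|*v1 + (1-rho)*|g4|*v2``.

The quantum step then pulls each candidate toward a per-candidate attractor
``Omega = theta*pbest_j + (1-theta)*gbest`` with a heavy-tailed jump
``Z = Omega -/+ beta * |Gbest_mean - V_j| * ln(1/u)``, where ``Gbest_mean``
is the mean of all personal bests and ``beta`` contracts linearly from 1.0
to 0.5 over the run.

Both proposals are accepted greedily (strictly lower cost only), so the
best-so-far cost is monotone nonincreasing. For feature selection,
positions live in [0, 1]^D, are binarized at 0.5, and are scored by the
wrapper cost 0.99 * (1 - cv_accuracy) + 0.01 * (selected / D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

FITNESS_WEIGHT_ERROR = 0.99
FITNESS_WEIGHT_RATIO = 0.01


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float = np.inf


@dataclass
class Population:
    candidates: list[Candidate]
    bounds: tuple[float, float]
    iteration: int = 0

    @property
    def best(self) -> int:
        return int(np.argmin([c.fitness for c in self.candidates]))

    @property
    def best_candidate(self) -> Candidate:
        return self.candidates[self.best]

    @property
    def mean_position(self) -> np.ndarray:
        return np.mean([c.position for c in self.candidates], axis=0)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class QuantumState:
    """Per-candidate personal bests and the global best."""

    pbest: np.ndarray          # (n, D)
    pbest_fitness: np.ndarray  # (n,)
    gbest: np.ndarray          # (D,)
    gbest_fitness: float

    @property
    def gbest_mean(self) -> np.ndarray:
        return self.pbest.mean(axis=0)

    def update(self, j: int, position: np.ndarray, fitness: float) -> None:
        if fitness < self.pbest_fitness[j]:
            self.pbest[j] = position
            self.pbest_fitness[j] = fitness
        if fitness < self.gbest_fitness:
            self.gbest = position.copy()
            self.gbest_fitness = fitness


@dataclass
class SelectionResult:
    mask: np.ndarray
    cost: float
    accuracy: float
    history: list[float]
    n_selected: int = 0
    fitness_ratio: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.n_selected = int(self.mask.sum())


def _clamp(z: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(z, bounds[0], bounds[1])


def init_population(n: int, d: int, bounds: tuple[float, float],
                    seed_or_rng) -> Population:
    """Uniform initialization Z = Zmin + r * (Zmax - Zmin), r ~ U(0,1)."""
    if n < 4:
        raise ValueError("population size must be >= 4 "
                         "(global exploration draws 3 distinct others)")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) \
        else seed_or_rng
    lo, hi = bounds
    positions = lo + rng.random((n, d)) * (hi - lo)
    return Population([Candidate(p) for p in positions], bounds=bounds)


def penalty_factor(gamma1: float, gamma2: float, x: float, y: float) -> float:
    """Signed penalty CT: -ln(g1)*cos(2*pi*g2) if x <= y, phase-shifted by
    pi otherwise (i.e. the two branches are negations of each other)."""
    if not 0.0 < gamma1 <= 1.0:
        raise ValueError("gamma1 must lie in (0, 1] (log singularity at 0)")
    phase = 0.0 if x <= y else np.pi
    return float(-np.log(gamma1) * np.cos(2.0 * np.pi * gamma2 + phase))


def local_exploitation(pop: Population, j: int,
                       rng: np.random.Generator) -> Candidate:
    """Trial around the generalized mean of {V_j, V_best, K}."""
    vj = pop.candidates[j].position
    vbest = pop.best_candidate.position
    k = pop.mean_position
    mean = (vj + vbest + k) / 3.0
    var = ((vj - mean) ** 2 + (vbest - mean) ** 2 + (k - mean) ** 2) / 3.0
    std = np.sqrt(var)
    ct = penalty_factor(rng.uniform(np.nextafter(0.0, 1.0), 1.0), rng.random(),
                        rng.random(), rng.random())
    z = mean + std * ct
    return Candidate(_clamp(z, pop.bounds))


def global_exploration(pop: Population, j: int,
                       rng: np.random.Generator) -> Candidate:
    """Trial mixing screened differences of three distinct random others."""
    n = len(pop)
    if n < 4:
        raise ValueError("global exploration needs a population of >= 4")
    others = [i for i in range(n) if i != j]
    l1, l2, l3 = rng.choice(others, size=3, replace=False)
    cands = pop.candidates
    vj = cands[j].position
    if cands[j].fitness < cands[l1].fitness:
        v1 = vj - cands[l1].position
    else:
        v1 = cands[l1].position - vj
    if cands[l2].fitness < cands[l3].fitness:
        v2 = cands[l2].position - cands[l3].position
    else:
        v2 = cands[l3].position - cands[l2].position
    rho = rng.random()
    g3, g4 = rng.normal(), rng.normal()
    z = vj + rho * abs(g3) * v1 + (1.0 - rho) * abs(g4) * v2
    return Candidate(_clamp(z, pop.bounds))


def quantum_update(state: QuantumState, pop: Population, j: int,
                   rng: np.random.Generator, beta: float = 1.0) -> Candidate:
    """Heavy-tailed jump toward the attractor between pbest_j and gbest."""
    vj = pop.candidates[j].position
    theta = rng.random()
    omega = theta * state.pbest[j] + (1.0 - theta) * state.gbest
    u = rng.uniform(np.nextafter(0.0, 1.0), 1.0)
    t = rng.random()
    step = beta * np.abs(state.gbest_mean - vj) * np.log(1.0 / u)
    z = omega - step if t > 0.5 else omega + step
    return Candidate(_clamp(z, pop.bounds))


def qgndo_minimize(fn: Callable[[np.ndarray], float], d: int,
                   bounds: tuple[float, float] = (0.0, 1.0),
                   n: int = 20, iters: int = 50, seed: int = 0,
                   beta_schedule: tuple[float, float] = (1.0, 0.5)):
    """Hybrid GNDO + quantum minimization of ``fn`` over a box.

    Per candidate per iteration: a fair coin picks local exploitation or
    global exploration, then a quantum jump follows; each proposal replaces
    the candidate only on strict improvement. Returns
    ``(best_position, best_cost, history, fitness_ratio)`` where ``history``
    is the best cost after every iteration (monotone nonincreasing) and
    ``fitness_ratio`` the per-iteration mean diagnostic
    ``|f(best) / f(candidate)|``.
    """
    rng = np.random.default_rng(seed)
    pop = init_population(n, d, bounds, rng)
    for c in pop.candidates:
        c.fitness = float(fn(c.position))
    state = QuantumState(
        pbest=np.stack([c.position.copy() for c in pop.candidates]),
        pbest_fitness=np.array([c.fitness for c in pop.candidates]),
        gbest=pop.best_candidate.position.copy(),
        gbest_fitness=pop.best_candidate.fitness,
    )
    history: list[float] = []
    ratios: list[float] = []
    b_hi, b_lo = beta_schedule
    for it in range(iters):
        beta = b_hi - (b_hi - b_lo) * (it / max(iters - 1, 1))
        pop.iteration = it
        for j in range(n):
            if rng.random() < 0.5:
                trial = local_exploitation(pop, j, rng)
            else:
                trial = global_exploration(pop, j, rng)
            trial.fitness = float(fn(trial.position))
            if trial.fitness < pop.candidates[j].fitness:
                pop.candidates[j] = trial
            state.update(j, pop.candidates[j].position,
                         pop.candidates[j].fitness)
            qtrial = quantum_update(state, pop, j, rng, beta=beta)
            qtrial.fitness = float(fn(qtrial.position))
            if qtrial.fitness < pop.candidates[j].fitness:
                pop.candidates[j] = qtrial
            state.update(j, pop.candidates[j].position,
                         pop.candidates[j].fitness)
        history.append(state.gbest_fitness)
        with np.errstate(divide="ignore", invalid="ignore"):
            fs = np.array([c.fitness for c in pop.candidates])
            r = np.abs(np.where(fs != 0, state.gbest_fitness / fs, 1.0))
        ratios.append(float(np.mean(r)))
    return state.gbest.copy(), float(state.gbest_fitness), history, ratios


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return position > threshold


def fitness(mask: np.ndarray, X, y, classifier_cfg: dict | None = None,
            folds: int = 5) -> float:
    """Wrapper cost 0.99 * (1 - cv_accuracy) + 0.01 * (selected / D).

    An empty mask is assigned the worst cost 1.0 (keeps the search total
    instead of raising).
    """
    from .classify import crossval_accuracy

    mask = np.asarray(mask, dtype=bool)
    d = mask.size
    k = int(mask.sum())
    if k == 0:
        return 1.0
    cfg = dict(classifier_cfg or {})
    preset = cfg.pop("preset", "narrow")
    values = np.asarray(getattr(X, "values", X), dtype=np.float64)
    acc = crossval_accuracy(values[:, mask], np.asarray(y), preset=preset,
                            folds=folds, **cfg)
    return FITNESS_WEIGHT_ERROR * (1.0 - acc) + FITNESS_WEIGHT_RATIO * (k / d)


def select_features(X, y, n: int = 20, iters: int = 30, seed: int = 0,
                    classifier_cfg: dict | None = None, folds: int = 5,
                    bounds: tuple[float, float] = (0.0, 1.0),
                    threshold: float = 0.5) -> SelectionResult:
    """Binary wrapper feature selection with the hybrid Q-GNDO search.

    Fitness values are cached per binary mask, so repeated visits to the
    same subset cost nothing. Deterministic given ``seed``.
    """
    values = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(y)
    if values.size == 0:
        raise ValueError("X must be nonempty")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    d = values.shape[1]
    cache: dict[bytes, float] = {}

    def cost(position: np.ndarray) -> float:
        mask = binarize(position, threshold)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = fitness(mask, values, y, classifier_cfg, folds)
        return cache[key]

    best, best_cost, history, ratios = qgndo_minimize(
        cost, d, bounds=bounds, n=n, iters=iters, seed=seed)
    best_mask = binarize(best, threshold)
    if not best_mask.any():
        # pathological but possible at iters=0: fall back to the single
        # highest coordinate so the result always selects >= 1 column
        best_mask = np.zeros(d, dtype=bool)
        best_mask[int(np.argmax(best))] = True
        best_cost = fitness(best_mask, values, y, classifier_cfg, folds)
    k = int(best_mask.sum())
    accuracy = 1.0 - (best_cost - FITNESS_WEIGHT_RATIO * k / d) / FITNESS_WEIGHT_ERROR
    return SelectionResult(mask=best_mask, cost=best_cost,
                           accuracy=float(100.0 * accuracy),
                           history=history, fitness_ratio=ratios)
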