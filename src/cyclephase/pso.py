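"""Particle swarm optimizer with fitness-adaptive inertia and CV fitness.

Velocity and position updates:

    V <- w V + c1 r1 (pbest - x) + c2 r2 (gbest - x)
    x <- x + V

with r1, r2 drawn i.i.d. uniform(0,1) per dimension, velocities clamped to
half the search range and positions clamped to the bounds.  The inertia
weight is adapted per particle from its fitness K relative to the swarm's
minimum and mean fitness this iteration:

    w = (w_max - w_min) (K - K_min) / (K_avg - K_min) + w_min   if K <= K_avg
    w = w_max                                                   if K >  K_avg

This piecewise rule treats K as a quantity being *minimized* (the particle
at the swarm minimum gets w_min and fine-tunes; at or above average it
gets w_max and keeps exploring), so the optimizer -- which maximizes --
feeds it the negated fitness by default.  ``literal_inertia`` instead
feeds the raw fitness, handing better-than-average particles the larger
inertia; that reading stalls the swarm's final convergence.  Default swarm
settings: 20 particles, 200 iterations, local acceleration c1 = 1.5,
global acceleration c2 = 1.7, inertia bounds 0.9 / 0.4.

For (C, gamma) tuning of the phase tree the fitness is the K-fold
(default ten-fold) cross-validation recognition rate

    H = (1/K) sum_l P_lr / (P_lr + P_lw)

with P_lr / P_lw the correctly / wrongly classified samples of fold l.
The (C, gamma) search runs in log10 coordinates over C in [1e-2, 1e2] and
gamma in [1e-3, 1e1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import LabeledDataset
from .svm import train_tree, predict_tree

__all__ = [
    "Particle",
    "SwarmConfig",
    "FitnessSpec",
    "OptimizeResult",
    "update_velocity",
    "update_position",
    "adaptive_inertia",
    "cv_fitness",
    "optimize",
    "tune_tree_params",
    "DEFAULT_LOG_BOUNDS",
]

# log10 search box for (C, gamma)
DEFAULT_LOG_BOUNDS = (np.array([-2.0, -3.0]), np.array([2.0, 1.0]))


class ConfigurationError(ValueError):
    pass


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    pbest_x: np.ndarray
    pbest_f: float = -np.inf


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm settings; the defaults are the tuning experiment's values."""

    n_particles: int = 20
    max_iter: int = 200
    c1: float = 1.5
    c2: float = 1.7
    omega_max: float = 0.9
    omega_min: float = 0.4
    bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_LOG_BOUNDS
    velocity_clamp: np.ndarray | None = None  # default: 0.5 * range per dim
    seed: int = 0
    patience: int = 30  # early stop: no gbest gain > tol for this many iters
    tol: float = 1e-6
    literal_inertia: bool = False  # feed raw fitness (not cost) to Eq.-7 rule

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ConfigurationError("swarm size must be >= 2")
        if self.omega_min > self.omega_max:
            raise ConfigurationError("omega_min must be <= omega_max")
        if self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("acceleration constants must be >= 0")
        lo, hi = (np.asarray(b, dtype=float) for b in self.bounds)
        if lo.shape != hi.shape or np.any(hi <= lo):
            raise ConfigurationError("infeasible bounds")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.bounds[0], dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.bounds[1], dtype=float)

    @property
    def v_max(self) -> np.ndarray:
        if self.velocity_clamp is not None:
            return np.asarray(self.velocity_clamp, dtype=float)
        return 0.5 * (self.hi - self.lo)


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    v_max: np.ndarray | None = None,
) -> np.ndarray:
    """New velocity from inertia, cognitive and social pulls (clamped)."""
    d = len(particle.x)
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    v = (
        omega * particle.v
        + c1 * r1 * (particle.pbest_x - particle.x)
        + c2 * r2 * (gbest - particle.x)
    )
    if v_max is not None:
        v = np.clip(v, -np.asarray(v_max), np.asarray(v_max))
    return v


def update_position(
    particle: Particle, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> np.ndarray:
    """x <- x + V, clamped to the search box."""
    x = particle.x + particle.v
    if bounds is not None:
        x = np.clip(x, bounds[0], bounds[1])
    return x


def adaptive_inertia(
    K_fit: float,
    K_min: float,
    K_avg: float,
    omega_max: float = 0.9,
    omega_min: float = 0.4,
) -> float:
    """Adaptive inertia weight (piecewise rule above), applied exactly as
    written to whatever scale K lives on.

    Degenerate swarm (K_avg == K_min, all values equal) returns omega_min.
    The result is always inside [omega_min, omega_max].
    """
    if K_min > K_avg:
        raise ValueError("K_min cannot exceed K_avg")
    if K_fit > K_avg:
        omega = omega_max
    elif K_avg == K_min:
        omega = omega_min
    else:
        omega = (omega_max - omega_min) * (K_fit - K_min) / (K_avg - K_min) + omega_min
    return min(max(omega, omega_min), omega_max)


@dataclass
class FitnessSpec:
    """K-fold CV recognition-rate fitness for a classifier family.

    ``family`` is either ``"svm-tree"`` (the phase tree retrained per fold
    with the candidate (C, gamma)) or a callable ``factory(position)``
    returning an object with ``fit(X, y)`` and ``predict(X)``; a fixed
    (weight-encoded) model may simply ignore ``fit``.
    """

    dataset: LabeledDataset
    n_folds: int = 10
    family: str | Callable = "svm-tree"
    kernel_kind: str = "rbf"
    fold_seed: int = 0

    def folds(self):
        y = self.dataset.y
        counts = np.bincount(y)[1:]
        if (counts[counts > 0] < self.n_folds).any():
            raise ValueError(
                f"every class needs >= {self.n_folds} samples for "
                f"{self.n_folds}-fold CV"
            )
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.fold_seed
        )
        return skf.split(self.dataset.X, y)


def cv_fitness(position: Sequence[float], spec: FitnessSpec) -> float:
    """H = mean over folds of (correct / (correct + wrong)) on the fold's
    validation part; in [0, 1] and invariant to fold order."""
    ds = spec.dataset
    accs = []
    for train_idx, val_idx in spec.folds():
        if spec.family == "svm-tree":
            C, gamma = float(position[0]), float(position[1])
            model = train_tree(ds.subset(train_idx), (C, gamma), kind=spec.kernel_kind)
            pred = predict_tree(model, ds.X[val_idx])
        else:
            clf = spec.family(np.asarray(position, dtype=float))
            clf.fit(ds.X[train_idx], ds.y[train_idx])
            pred = clf.predict(ds.X[val_idx])
        correct = int(np.sum(pred == ds.y[val_idx]))
        wrong = len(val_idx) - correct
        accs.append(correct / (correct + wrong))
    return float(np.mean(accs))


@dataclass
class OptimizeResult:
    best_x: np.ndarray
    best_f: float
    trace: np.ndarray  # gbest fitness per iteration (non-decreasing)
    n_iter: int


def optimize(objective: Callable, config: SwarmConfig) -> OptimizeResult:
    """Maximize ``objective(x)`` over the search box.

    Runs for ``max_iter`` iterations or until the global best has not
    improved by more than ``tol`` for ``patience`` consecutive iterations.
    Fitness ties are broken by lower particle index; with a fixed seed the
    whole trajectory is reproducible bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi, v_max = config.lo, config.hi, config.v_max
    d = len(lo)

    particles = []
    for _ in range(config.n_particles):
        x = rng.uniform(lo, hi)
        v = rng.uniform(-v_max, v_max)
        particles.append(Particle(x=x, v=v, pbest_x=x.copy()))

    gbest_x = particles[0].x.copy()
    gbest_f = -np.inf
    trace = []
    stall = 0
    n_iter = 0

    for _ in range(config.max_iter):
        n_iter += 1
        fitness = np.array([objective(p.x) for p in particles])
        improved = gbest_f
        for i, p in enumerate(particles):
            if fitness[i] > p.pbest_f:
                p.pbest_f = fitness[i]
                p.pbest_x = p.x.copy()
            if fitness[i] > gbest_f:  # strict: ties keep the earlier holder
                gbest_f = float(fitness[i])
                gbest_x = p.x.copy()
        trace.append(gbest_f)

        stall = 0 if gbest_f - improved > config.tol else stall + 1
        if stall >= config.patience:
            break

        # the inertia rule minimizes its K; feed it the cost (negated
        # fitness) unless the literal raw-fitness reading was requested
        K = fitness if config.literal_inertia else -fitness
        K_min = float(K.min())
        K_avg = float(K.mean())
        for p, k in zip(particles, K):
            omega = adaptive_inertia(
                float(k), K_min, K_avg, config.omega_max, config.omega_min
            )
            p.v = update_velocity(p, gbest_x, omega, config.c1, config.c2, rng, v_max)
            p.x = update_position(p, (lo, hi))

    return OptimizeResult(
        best_x=gbest_x, best_f=float(gbest_f), trace=np.array(trace), n_iter=n_iter
    )


def tune_tree_params(
    ds: LabeledDataset,
    swarm: SwarmConfig | None = None,
    n_folds: int = 10,
    kernel_kind: str = "rbf",
    per_node: bool = False,
) -> tuple[tuple, float, np.ndarray]:
    """PSO-tune (C, gamma) for the phase tree by CV recognition rate.

    Searches log10(C), log10(gamma); one shared pair by default, or -- with
    ``per_node`` -- a 6-dimensional search giving each tree node its own
    pair.  Returns ((C, gamma) [or three pairs], best CV fitness, gbest
    fitness trace).
    """
    swarm = swarm or SwarmConfig()
    spec = FitnessSpec(dataset=ds, n_folds=n_folds, kernel_kind=kernel_kind,
                       fold_seed=swarm.seed)
    if per_node:
        lo = np.tile(swarm.lo, 3)
        hi = np.tile(swarm.hi, 3)
        swarm = dataclasses.replace(swarm, bounds=(lo, hi), velocity_clamp=None)

        def objective(pos):
            pairs = [(10.0 ** pos[2 * i], 10.0 ** pos[2 * i + 1]) for i in range(3)]
            return _cv_fitness_pairs(pairs, spec)

    else:
        def objective(pos):
            return cv_fitness((10.0 ** pos[0], 10.0 ** pos[1]), spec)

    res = optimize(objective, swarm)
    if per_node:
        params = tuple(
            (10.0 ** res.best_x[2 * i], 10.0 ** res.best_x[2 * i + 1]) for i in range(3)
        )
    else:
        params = (10.0 ** res.best_x[0], 10.0 ** res.best_x[1])
    return params, res.best_f, res.trace


def _cv_fitness_pairs(pairs, spec: FitnessSpec) -> float:
    ds = spec.dataset
    accs = []
    for train_idx, val_idx in spec.folds():
        model = train_tree(ds.subset(train_idx), pairs, kind=spec.kernel_kind)
        pred = predict_tree(model, ds.X[val_idx])
        accs.append(float(np.mean(pred == ds.y[val_idx])))
    return float(np.mean(accs))
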