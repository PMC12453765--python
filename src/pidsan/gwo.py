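"""Grey wolf optimization (GWO) over a mixed hyperparameter space.

GWO is a population metaheuristic: a pack of candidate solutions ("wolves")
moves toward the average of the three best solutions found so far (the
alpha, beta and delta leaders).  For each wolf and leader, a displacement
Phi = |C * w_leader - w| is computed with a random coefficient C in [0, 2],
and the candidate moves to w_leader - T * Phi, where the attack coefficient
T is drawn uniformly from [-tau, tau] with tau decaying linearly from 2 to 0
over the iteration budget; the new position is the mean of the three
leader-driven proposals.  Early iterations (|T| often > 1) explore; late
iterations converge onto the leaders.

The search runs in internal [0, 1] coordinates; each dimension decodes to
its native range (linear or log scale, integer rounding, or a categorical
label), so heterogeneous hyperparameters share one arithmetic.  The default
space covers learning rate (log [0.00021, 1]), section depth
(linear [0.001, 2.914], rounded to an integer >= 1), L2 regularization
(log [1e-7, 1e-1]), activation type ({ReLU, Sigmoid, Clipped ReLU}) and
dropout (linear [0.24, 0.91]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContinuousDim", "CategoricalDim", "SearchSpace", "WolfPack",
    "GwoCoefficients", "GwoResult", "tau_schedule", "sample_coefficients",
    "gwo_step", "gwo_optimize", "tune_model",
]


# -- search space -------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousDim:
    name: str
    lo: float
    hi: float
    scale: str = "linear"          # "linear" | "log"
    integer: bool = False          # round decoded value to nearest int >= 1

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: need lo < hi, got [{self.lo}, {self.hi}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError(f"{self.name}: log scale requires lo > 0")

    def decode(self, u: float):
        u = min(max(float(u), 0.0), 1.0)
        if self.scale == "log":
            value = math.exp(math.log(self.lo) + u * (math.log(self.hi) - math.log(self.lo)))
        else:
            value = self.lo + u * (self.hi - self.lo)
        value = min(max(value, self.lo), self.hi)   # guard float round-off
        if self.integer:
            return max(1, int(round(value)))
        return value


@dataclass(frozen=True)
class CategoricalDim:
    name: str
    labels: tuple

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError(f"{self.name}: label list must be non-empty")

    def decode(self, u: float):
        idx = int(float(u) * len(self.labels))
        return self.labels[min(idx, len(self.labels) - 1)]


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple

    def __post_init__(self):
        if len(self.dimensions) == 0:
            raise ValueError("search space needs at least one dimension")

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def decode(self, position: np.ndarray) -> dict:
        position = np.asarray(position, dtype=np.float64)
        if position.shape != (self.ndim,):
            raise ValueError(f"position must have shape ({self.ndim},), got {position.shape}")
        return {d.name: d.decode(u) for d, u in zip(self.dimensions, position)}

    @classmethod
    def default(cls) -> "SearchSpace":
        """The standard five-dimensional tuning space for both networks."""
        return cls(dimensions=(
            ContinuousDim("learning_rate", 0.00021, 1.0, scale="log"),
            ContinuousDim("section_depth", 0.001, 2.914, scale="linear", integer=True),
            ContinuousDim("l2", 1e-7, 1e-1, scale="log"),
            CategoricalDim("activation", ("ReLU", "Sigmoid", "Clipped ReLU")),
            ContinuousDim("dropout", 0.24, 0.91, scale="linear"),
        ))


def decode_position(position: np.ndarray, space: SearchSpace) -> dict:
    return space.decode(position)


# -- coefficients -------------------------------------------------------------

def tau_schedule(iteration: int, max_iter: int) -> float:
    """Linear decay of the exploration envelope from 2 (first) to 0 (last)."""
    if max_iter < 2:
        raise ValueError(f"max_iter must be >= 2, got {max_iter}")
    if not 0 <= iteration < max_iter:
        raise ValueError(f"iteration {iteration} outside [0, {max_iter})")
    return 2.0 * (1.0 - iteration / (max_iter - 1))


@dataclass(frozen=True)
class GwoCoefficients:
    """Per-dimension random coefficients: c1 in [-tau, tau], c2 in [0, 2]."""
    tau: float
    c1: np.ndarray
    c2: np.ndarray


def sample_coefficients(tau: float, rng: np.random.Generator,
                        ndim: int = 1) -> GwoCoefficients:
    if not 0.0 <= tau <= 2.0:
        raise ValueError(f"tau must be in [0, 2], got {tau}")
    r1 = rng.random(ndim)
    r2 = rng.random(ndim)
    return GwoCoefficients(tau=tau, c1=2.0 * tau * r1 - tau, c2=2.0 * r2)


# -- pack state ---------------------------------------------------------------

@dataclass
class Leader:
    position: np.ndarray
    fitness: float
    order: int                      # discovery index; earliest wins ties


@dataclass
class WolfPack:
    positions: np.ndarray           # (n_wolves, ndim) in internal [0, 1]
    fitnesses: np.ndarray           # (n_wolves,)
    leaders: list                   # [alpha, beta, delta], best-ever archive
    iteration: int
    max_iter: int
    rng: np.random.Generator
    n_evaluated: int = 0
    events: list = field(default_factory=list)

    @property
    def alpha(self) -> Leader:
        return self.leaders[0]


def _update_leaders(leaders: list, candidates: list, keep: int = 3) -> list:
    pool = list(leaders) + list(candidates)
    pool.sort(key=lambda L: (-L.fitness, L.order))
    return pool[:keep]


def _evaluate(pack: WolfPack, objective) -> np.ndarray:
    """Evaluate all wolves; a failing/non-finite objective keeps the old fitness
    (first evaluation: -inf) and records the event."""
    fits = np.empty(len(pack.positions))
    for i, pos in enumerate(pack.positions):
        try:
            value = float(objective(pos))
        except Exception as exc:       # noqa: BLE001 - objective is user code
            pack.events.append(f"iter {pack.iteration}: wolf {i} objective failed: {exc!r}")
            value = pack.fitnesses[i] if np.isfinite(pack.fitnesses[i]) else -np.inf
        if not np.isfinite(value):
            value = -np.inf
        fits[i] = value
        pack.n_evaluated += 1
    return fits


def init_pack(objective, ndim: int, n_wolves: int, max_iter: int,
              seed=None) -> WolfPack:
    rng = np.random.default_rng(seed)
    positions = rng.random((n_wolves, ndim))
    pack = WolfPack(positions=positions, fitnesses=np.full(n_wolves, -np.inf),
                    leaders=[], iteration=0, max_iter=max_iter, rng=rng)
    pack.fitnesses = _evaluate(pack, objective)
    candidates = [Leader(p.copy(), f, i)
                  for i, (p, f) in enumerate(zip(positions, pack.fitnesses))]
    pack.leaders = _update_leaders([], candidates)
    while len(pack.leaders) < 3:        # tiny packs: duplicate the best
        pack.leaders.append(pack.leaders[-1])
    return pack


def gwo_step(pack: WolfPack, objective) -> WolfPack:
    """One position update + re-evaluation + leader refresh (in place)."""
    if not pack.leaders:
        raise ValueError("pack leaders must be populated before stepping")
    tau = tau_schedule(pack.iteration, pack.max_iter)
    n, ndim = pack.positions.shape
    new_positions = np.empty_like(pack.positions)
    for i in range(n):
        w = pack.positions[i]
        proposals = np.empty((3, ndim))
        for j, leader in enumerate(pack.leaders[:3]):
            coeff = sample_coefficients(tau, pack.rng, ndim)
            phi = np.abs(coeff.c2 * leader.position - w)
            proposals[j] = leader.position - coeff.c1 * phi
        new_positions[i] = np.clip(proposals.mean(axis=0), 0.0, 1.0)
    pack.positions = new_positions
    pack.iteration += 1
    base_order = pack.n_evaluated
    pack.fitnesses = _evaluate(pack, objective)
    candidates = [Leader(p.copy(), f, base_order + i)
                  for i, (p, f) in enumerate(zip(new_positions, pack.fitnesses))]
    pack.leaders = _update_leaders(pack.leaders, candidates)
    return pack


@dataclass
class GwoResult:
    best_params: dict
    best_fitness: float
    best_position: np.ndarray
    history: list                   # alpha fitness after init and each step
    n_evaluations: int
    events: list


def gwo_optimize(objective, space: SearchSpace, n_wolves: int = 10,
                 max_iter: int = 20, seed=None) -> GwoResult:
    """Maximize ``objective(decoded_hyperparameters)`` over the search space.

    The objective is called at most ``n_wolves * (max_iter + 1)`` times.  The
    returned history (alpha-leader fitness after initialisation and after
    each step) is non-decreasing because leaders are a best-ever archive.
    Identical seeds give identical trajectories.
    """

    def internal_objective(position):
        return objective(space.decode(position))

    pack = init_pack(internal_objective, space.ndim, n_wolves, max_iter, seed)
    history = [pack.alpha.fitness]
    for _ in range(max_iter):
        gwo_step(pack, internal_objective)
        history.append(pack.alpha.fitness)
    alpha = pack.alpha
    return GwoResult(best_params=space.decode(alpha.position),
                     best_fitness=alpha.fitness,
                     best_position=alpha.position.copy(),
                     history=history,
                     n_evaluations=pack.n_evaluated,
                     events=pack.events)


def tune_model(model_builder, data_bundle, space: SearchSpace | None = None,
               n_wolves: int = 10, max_iter: int = 20, seed=None,
               train_fn=None) -> GwoResult:
    """Tune hyperparameters by maximizing short-training validation accuracy.

    ``model_builder(hyperparams) -> model`` constructs a fresh model for a
    decoded hyperparameter set and ``train_fn(model, data_bundle,
    hyperparams) -> float`` trains it briefly and returns validation
    accuracy (default: :func:`pidsan.train_eval.quick_validation_accuracy`).
    A diverging or failing evaluation scores -inf and the search continues.
    Every evaluation is recorded in ``result.audit`` as (hyperparams, score).
    """
    space = space or SearchSpace.default()
    if train_fn is None:
        from .train_eval import quick_validation_accuracy
        train_fn = quick_validation_accuracy
    audit = []

    def objective(hyperparams: dict) -> float:
        try:
            model = model_builder(hyperparams)
            score = float(train_fn(model, data_bundle, hyperparams))
        except (FloatingPointError, ValueError, OverflowError):
            score = -np.inf
        audit.append((dict(hyperparams), score))
        return score

    result = gwo_optimize(objective, space, n_wolves=n_wolves,
                          max_iter=max_iter, seed=seed)
    result.audit = audit
    return result
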