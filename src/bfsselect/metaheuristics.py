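"""Swarm baselines: binary PSO / GWO / WOA for feature selection and their
continuous forms for hyperparameter tuning.

The canonical published update rules are used (Kennedy-Eberhart particle
swarm with linearly scheduled inertia, Mirjalili grey-wolf alpha/beta/delta
hierarchy with `a` decreasing linearly 2 -> 0, and Mirjalili whale
encircling/spiral with the p = 0.5 branch).  Binarization is stochastic:
a bit is set iff a uniform draw falls below a sigmoid transfer of the
continuous state — the velocity for PSO, a sharpened centred position
10*(x - 0.5) for GWO/WOA, whose positions live near {0, 1}.  All-zero masks
are repaired by setting one uniformly chosen bit.  A single NumPy generator
seeded per run drives initialization, binarization and repair, so every
trace is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .bfs import HyperGraph, SearchTrace
from .models import (
    ClassifierSpec,
    FitnessRecord,
    evaluate_config,
    fitness_accuracy,
    fitness_composite,
)
from .preprocess import SplitPair

__all__ = [
    "SwarmConfig",
    "REFERENCE_PARAMS",
    "transfer_sigmoid",
    "binary_optimize",
    "continuous_tune",
]

BINARY_ALGORITHMS = ("BPSO", "BGWO", "BWOA")
CONTINUOUS_ALGORITHMS = ("PSO", "GWO", "WOA")

#: Reference run configurations (population sizes, iteration counts, PSO
#: acceleration) conventionally used when comparing these optimizers on
#: small tabular problems.  The reference PSO acceleration [5, 5] is
#: implausibly aggressive for standard PSO; the package default is
#: c1 = c2 = 2.0.
REFERENCE_PARAMS = {
    "BPSO": {"population": 50, "iterations": 100, "pso_acceleration": (5.0, 5.0)},
    "PSO": {"population": 50, "iterations": 100, "pso_acceleration": (5.0, 5.0)},
    "BWOA": {"population": 200, "iterations": 100},
    "WOA": {"population": 200, "iterations": 100},
    "BGWO": {"population": 20, "iterations": 100},
    "GWO": {"population": 20, "iterations": 100},
}

#: Position-binarization sharpening: bit probability sigmoid(GAIN*(x-0.5)).
POSITION_GAIN = 10.0


@dataclass
class SwarmConfig:
    """Run parameters of one swarm optimizer.

    ``pso_inertia_bounds`` = (w_min, w_max); inertia is scheduled linearly
    from w_max down to w_min over the iterations.  ``vmax`` clamps PSO
    velocities so sigmoid probabilities stay off the saturation plateaus.
    ``max_evaluations`` optionally caps total fitness evaluations below
    population * iterations (equal-budget comparisons).
    """

    algorithm: str = "BPSO"
    population: int = 20
    iterations: int = 100
    pso_acceleration: tuple = (2.0, 2.0)
    pso_inertia_bounds: tuple = (0.5, 0.8)
    vmax: float = 6.0
    max_evaluations: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in BINARY_ALGORITHMS + CONTINUOUS_ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from "
                f"{BINARY_ALGORITHMS + CONTINUOUS_ALGORITHMS}"
            )
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        w_min, w_max = self.pso_inertia_bounds
        if w_min > w_max:
            raise ValueError("inertia bounds must be ordered (w_min <= w_max)")

    @classmethod
    def reference(cls, algorithm: str, seed: int = 0) -> "SwarmConfig":
        """The reference run configuration for an algorithm."""
        return cls(algorithm=algorithm, seed=seed, **REFERENCE_PARAMS[algorithm])


def transfer_sigmoid(v):
    """S-shaped transfer 1 / (1 + e^-v) mapping a real state to a bit probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def _inertia(cfg: SwarmConfig, t: int) -> float:
    w_min, w_max = cfg.pso_inertia_bounds
    frac = t / max(cfg.iterations - 1, 1)
    return w_max - (w_max - w_min) * frac


def _repair_zero_rows(bits: np.ndarray, rng: np.random.Generator) -> None:
    zero = bits.sum(axis=1) == 0
    for i in np.where(zero)[0]:
        bits[i, rng.integers(bits.shape[1])] = 1


def binary_optimize(
    split: SplitPair | None,
    spec: ClassifierSpec | None,
    cfg: SwarmConfig,
    alpha: float = 0.99,
    fitness_fn: Callable[[tuple], float] | None = None,
    d: int | None = None,
) -> SearchTrace:
    """Run a binary swarm optimizer over feature masks.

    Minimizes the composite fitness (or an injected ``fitness_fn``).  Every
    agent is evaluated every iteration, so the trace holds exactly
    population * iterations records unless ``max_evaluations`` caps it.
    """
    if cfg.algorithm not in BINARY_ALGORITHMS:
        raise ValueError(f"{cfg.algorithm!r} is not a binary algorithm")
    if split is not None:
        d = split.train.d
    elif fitness_fn is None or d is None:
        raise ValueError("without a split, both fitness_fn and d are required")
    spec = spec or ClassifierSpec()
    rng = np.random.default_rng(cfg.seed)

    if fitness_fn is not None:
        def evaluate(mask):
            return FitnessRecord(mask=mask, fitness=float(fitness_fn(mask)))
    else:
        spec_seeded = replace(spec, seed=cfg.seed)

        def evaluate(mask):
            rec = fitness_accuracy(mask, split, spec_seeded)
            rec.fitness = fitness_composite(rec, alpha)
            return rec

    trace = SearchTrace(seed=cfg.seed, algorithm=cfg.algorithm)
    budget = cfg.max_evaluations or cfg.population * cfg.iterations

    pop = cfg.population
    bits = (rng.random((pop, d)) < 0.5).astype(int)
    _repair_zero_rows(bits, rng)
    positions = bits.astype(float)  # continuous companion state (GWO/WOA)
    velocities = np.zeros((pop, d))
    fitness = np.full(pop, np.inf)
    pbest_bits = bits.copy()
    pbest_fit = np.full(pop, np.inf)
    gbest_bits = bits[0].copy()
    gbest_fit = np.inf
    c1, c2 = cfg.pso_acceleration

    for t in range(cfg.iterations):
        if trace.n_evaluations >= budget:
            break
        if t > 0:
            if cfg.algorithm == "BPSO":
                w = _inertia(cfg, t)
                r1 = rng.random((pop, d))
                r2 = rng.random((pop, d))
                velocities = (
                    w * velocities
                    + c1 * r1 * (pbest_bits - bits)
                    + c2 * r2 * (gbest_bits[None, :] - bits)
                )
                np.clip(velocities, -cfg.vmax, cfg.vmax, out=velocities)
                bits = (rng.random((pop, d)) < transfer_sigmoid(velocities)).astype(int)
            elif cfg.algorithm == "BGWO":
                a = 2.0 - 2.0 * t / max(cfg.iterations - 1, 1)
                order = np.argsort(fitness, kind="stable")[:3]
                leaders = bits[order].astype(float)
                parts = []
                for leader in leaders:
                    A = 2.0 * a * rng.random((pop, d)) - a
                    C = 2.0 * rng.random((pop, d))
                    D = np.abs(C * leader[None, :] - positions)
                    parts.append(leader[None, :] - A * D)
                positions = np.clip(np.mean(parts, axis=0), 0.0, 1.0)
                prob = transfer_sigmoid(POSITION_GAIN * (positions - 0.5))
                bits = (rng.random((pop, d)) < prob).astype(int)
            else:  # BWOA
                a = 2.0 - 2.0 * t / max(cfg.iterations - 1, 1)
                leader = gbest_bits.astype(float)
                new_pos = positions.copy()
                for i in range(pop):
                    if rng.random() < 0.5:
                        A = 2.0 * a * rng.random(d) - a
                        C = 2.0 * rng.random(d)
                        if np.all(np.abs(A) < 1.0):
                            ref = leader
                        else:
                            ref = positions[rng.integers(pop)]
                        D = np.abs(C * ref - positions[i])
                        new_pos[i] = ref - A * D
                    else:
                        l = rng.uniform(-1.0, 1.0)
                        D = np.abs(leader - positions[i])
                        new_pos[i] = D * math.exp(l) * math.cos(2.0 * math.pi * l) + leader
                positions = np.clip(new_pos, 0.0, 1.0)
                prob = transfer_sigmoid(POSITION_GAIN * (positions - 0.5))
                bits = (rng.random((pop, d)) < prob).astype(int)
            _repair_zero_rows(bits, rng)
            if cfg.algorithm == "BPSO":
                positions = bits.astype(float)

        for i in range(pop):
            if trace.n_evaluations >= budget:
                break
            rec = evaluate(tuple(int(b) for b in bits[i]))
            trace.record(rec)
            fitness[i] = rec.fitness
            if rec.fitness < pbest_fit[i]:
                pbest_fit[i] = rec.fitness
                pbest_bits[i] = bits[i]
            if rec.fitness < gbest_fit:
                gbest_fit = rec.fitness
                gbest_bits = bits[i].copy()
    return trace


def continuous_tune(
    graph: HyperGraph,
    mask,
    split: SplitPair | None,
    cfg: SwarmConfig,
    folds: int = 10,
    spec: ClassifierSpec | None = None,
    score_fn: Callable[[object], float] | None = None,
) -> SearchTrace:
    """Continuous swarm hyperparameter tuning over a grid's bounding box.

    Particles move in the box spanned by the numeric encodings of the grid
    axes (unbounded depth encoded as axis maximum + 1, booleans as 1/0) and
    are snapped to the nearest grid point before each evaluation.  The
    objective is 1 - (cross-)validation accuracy, as for the BFS tuner.
    """
    if cfg.algorithm not in CONTINUOUS_ALGORITHMS:
        raise ValueError(f"{cfg.algorithm!r} is not a continuous algorithm")
    spec = spec or ClassifierSpec()
    mask = tuple(int(b) for b in mask) if mask is not None else ()
    rng = np.random.default_rng(cfg.seed)

    enc = graph.numeric_axes()
    axis_names = list(enc)
    axis_values = [np.asarray(enc[name]) for name in axis_names]
    lo = np.array([v.min() for v in axis_values])
    hi = np.array([v.max() for v in axis_values])
    span = np.where(hi > lo, hi - lo, 1.0)
    k = len(axis_names)

    def snap(point) -> "HyperConfig":
        idx = tuple(
            int(np.argmin(np.abs(vals - x))) for vals, x in zip(axis_values, point)
        )
        return graph.from_indices(idx)

    if score_fn is not None:
        def evaluate(config):
            score = float(score_fn(config))
            return FitnessRecord(mask=mask, fitness=1.0 - score, accuracy=score, hyper=config)
    else:
        def evaluate(config):
            rec = evaluate_config(config, mask, split, spec=spec, folds=folds, seed=cfg.seed)
            rec.fitness = 1.0 - rec.accuracy
            return rec

    trace = SearchTrace(seed=cfg.seed, algorithm=cfg.algorithm)
    budget = cfg.max_evaluations or cfg.population * cfg.iterations
    pop = cfg.population
    X = rng.uniform(lo, hi, size=(pop, k))
    V = np.zeros((pop, k))
    fitness = np.full(pop, np.inf)
    pbest = X.copy()
    pbest_fit = np.full(pop, np.inf)
    gbest = X[0].copy()
    gbest_fit = np.inf
    c1, c2 = cfg.pso_acceleration

    for t in range(cfg.iterations):
        if trace.n_evaluations >= budget:
            break
        if t > 0:
            if cfg.algorithm == "PSO":
                w = _inertia(cfg, t)
                r1 = rng.random((pop, k))
                r2 = rng.random((pop, k))
                V = w * V + c1 * r1 * (pbest - X) + c2 * r2 * (gbest[None, :] - X)
                np.clip(V, -cfg.vmax * span, cfg.vmax * span, out=V)
                X = X + V
            elif cfg.algorithm == "GWO":
                a = 2.0 - 2.0 * t / max(cfg.iterations - 1, 1)
                order = np.argsort(fitness, kind="stable")[:3]
                leaders = X[order]
                parts = []
                for leader in leaders:
                    A = 2.0 * a * rng.random((pop, k)) - a
                    C = 2.0 * rng.random((pop, k))
                    D = np.abs(C * leader[None, :] - X)
                    parts.append(leader[None, :] - A * D)
                X = np.mean(parts, axis=0)
            else:  # WOA
                a = 2.0 - 2.0 * t / max(cfg.iterations - 1, 1)
                new_X = X.copy()
                for i in range(pop):
                    if rng.random() < 0.5:
                        A = 2.0 * a * rng.random(k) - a
                        C = 2.0 * rng.random(k)
                        ref = gbest if np.all(np.abs(A) < 1.0) else X[rng.integers(pop)]
                        new_X[i] = ref - A * np.abs(C * ref - X[i])
                    else:
                        l = rng.uniform(-1.0, 1.0)
                        D = np.abs(gbest - X[i])
                        new_X[i] = D * math.exp(l) * math.cos(2.0 * math.pi * l) + gbest
                X = new_X
            X = np.clip(X, lo, hi)

        for i in range(pop):
            if trace.n_evaluations >= budget:
                break
            rec = evaluate(snap(X[i]))
            trace.record(rec)
            fitness[i] = rec.fitness
            if rec.fitness < pbest_fit[i]:
                pbest_fit[i] = rec.fitness
                pbest[i] = X[i]
            if rec.fitness < gbest_fit:
                gbest_fit = rec.fitness
                gbest = X[i].copy()
    return trace
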