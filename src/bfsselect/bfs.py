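"""Breadth-first search over the feature-subset lattice and hyperparameter grid.

Feature subsets are encoded as binary masks of length d (bit j = 1 keeps
feature j).  The feature selector (:func:`bbfs_select`) starts from the
all-ones mask — every feature considered — and explores single-bit-flip
neighbours level by level, scoring each visited mask with the wrapper
fitness and keeping the best ever seen.  The hyperparameter tuner
(:func:`bfs_tune`) runs the same traversal over a grid graph whose
neighbours differ in exactly one axis by one grid step, rooted at the
library-default configuration.

Both searches share one halting discipline: an evaluation budget, an
optional level cap, an optional beam width per level, and optional patience
(levels without best-fitness improvement).  Ties in fitness are broken in
favour of the earliest-evaluated state; successors are generated in a fixed
deterministic order, so a run is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

from .models import (
    ClassifierSpec,
    FitnessRecord,
    HyperConfig,
    evaluate_config,
    fitness_accuracy,
    fitness_composite,
)
from .preprocess import SplitPair

__all__ = [
    "BfsConfig",
    "SearchTrace",
    "HyperGraph",
    "successors",
    "bfs_minimize",
    "bbfs_select",
    "bfs_tune",
    "summarize_best_config",
    "default_rf_grid",
    "all_feasible_masks",
]

Mask = tuple


@dataclass
class BfsConfig:
    """Halting/width parameters of a breadth-first search.

    ``max_iterations`` is the total fitness-evaluation budget (the root
    counts).  ``beam_width`` keeps only the best states of each completed
    level in the frontier (None = unbounded).  ``patience`` halts after that
    many consecutive levels without improvement of the best fitness.
    ``graph_vertices``/``graph_edges`` are provenance metadata carried along
    with a run configuration; they do not drive the search.
    """

    max_iterations: int = 100
    max_levels: int | None = None
    beam_width: int | None = None
    patience: int | None = None
    graph_vertices: int = 5
    graph_edges: int = 6

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations (evaluation budget) must be >= 1")
        if self.beam_width is not None and self.beam_width < 1:
            raise ValueError("beam_width must be >= 1 when bounded")


@dataclass
class SearchTrace:
    """Complete record of one search run.

    ``best_so_far[i]`` is the minimum fitness after evaluation i+1; it is
    non-increasing by construction.  ``best`` is the earliest record
    attaining the final minimum.
    """

    evaluations: list[FitnessRecord] = field(default_factory=list)
    best_so_far: list[float] = field(default_factory=list)
    best: FitnessRecord | None = None
    seed: int = 0
    algorithm: str = ""

    def record(self, rec: FitnessRecord) -> None:
        self.evaluations.append(rec)
        if self.best is None or rec.fitness < self.best.fitness:
            self.best = rec
        self.best_so_far.append(self.best.fitness)

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)


def successors(mask: Mask, visited: Iterable[Mask] = (), removal_only: bool = False) -> list[Mask]:
    """Feasible, unvisited Hamming-distance-1 neighbours of a mask.

    Each single bit is flipped; all-zero masks are infeasible and dropped.
    With ``removal_only`` only 1 -> 0 flips are generated (the literal
    "iteratively removes features" reading).  Neighbours are returned in
    ascending lexicographic order of their bit vectors.
    """
    visited = set(visited)
    out = []
    for j in range(len(mask)):
        if removal_only and mask[j] == 0:
            continue
        flipped = mask[:j] + (1 - mask[j],) + mask[j + 1:]
        if sum(flipped) == 0 or flipped in visited:
            continue
        out.append(flipped)
    out.sort()
    return out


def bfs_minimize(
    root,
    expand: Callable[[object, set], list],
    evaluate: Callable[[object], FitnessRecord],
    cfg: BfsConfig | None = None,
    seed: int = 0,
    algorithm: str = "BFS",
) -> SearchTrace:
    """Generic level-order minimization engine shared by both searches.

    The root is evaluated first; each level's states are dequeued FIFO and
    their unvisited successors evaluated and enqueued (marked visited at
    enqueue time, so no state is ever evaluated twice).  A bounded beam
    keeps only the ``beam_width`` best of each completed level.
    """
    cfg = cfg or BfsConfig()
    trace = SearchTrace(seed=seed, algorithm=algorithm)
    visited = {root}
    trace.record(evaluate(root))
    frontier = [root]
    level = 0
    stall = 0
    while frontier and trace.n_evaluations < cfg.max_iterations:
        if cfg.max_levels is not None and level >= cfg.max_levels:
            break
        prev_best = trace.best.fitness
        next_frontier: list[tuple] = []
        exhausted = False
        for state in frontier:
            for succ in expand(state, visited):
                if trace.n_evaluations >= cfg.max_iterations:
                    exhausted = True
                    break
                visited.add(succ)
                trace.record(evaluate(succ))
                next_frontier.append((succ, trace.evaluations[-1].fitness))
            if exhausted:
                break
        level += 1
        if cfg.beam_width is not None:
            # stable sort: fitness ties keep evaluation order
            next_frontier.sort(key=lambda t: t[1])
            next_frontier = next_frontier[: cfg.beam_width]
        frontier = [s for s, _ in next_frontier]
        stall = 0 if trace.best.fitness < prev_best else stall + 1
        if cfg.patience is not None and stall >= cfg.patience:
            break
    return trace


def bbfs_select(
    split: SplitPair,
    spec: ClassifierSpec | None = None,
    cfg: BfsConfig | None = None,
    alpha: float = 0.99,
    seed: int = 0,
    fitness_fn: Callable[[Mask], float] | None = None,
    removal_only: bool = False,
    d: int | None = None,
) -> SearchTrace:
    """Binary breadth-first feature selection.

    Starts from the all-ones mask (all features considered) and minimizes
    the composite fitness alpha*(1-accuracy) + (1-alpha)*|S|/d.  An injected
    ``fitness_fn`` (mask -> objective) replaces model training, which makes
    the search checkable against exhaustive enumeration; pass ``d``
    explicitly when no split is supplied.
    """
    spec = spec or ClassifierSpec()
    if split is not None:
        d = split.train.d
    elif fitness_fn is None or d is None:
        raise ValueError("without a split, both fitness_fn and d are required")
    if d < 1:
        raise ValueError("need at least one feature")

    if fitness_fn is not None:
        def evaluate(mask):
            return FitnessRecord(mask=mask, fitness=float(fitness_fn(mask)))
    else:
        spec_seeded = replace(spec, seed=seed)

        def evaluate(mask):
            rec = fitness_accuracy(mask, split, spec_seeded)
            rec.fitness = fitness_composite(rec, alpha)
            return rec

    root = (1,) * d
    expand = lambda m, visited: successors(m, visited, removal_only=removal_only)
    return bfs_minimize(root, expand, evaluate, cfg, seed=seed, algorithm="BBFS")


@dataclass
class HyperGraph:
    """A hyperparameter grid with single-axis-step adjacency.

    ``axes`` maps :class:`HyperConfig` field names to ordered value lists;
    two configurations are neighbours iff they differ in exactly one axis by
    one position along that axis's list.
    """

    axes: dict
    root: HyperConfig = field(default_factory=HyperConfig)

    def __post_init__(self):
        bad = set(self.axes) - set(HyperConfig.__dataclass_fields__)
        if bad:
            raise ValueError(f"axes name unknown hyperparameters: {sorted(bad)}")
        self.indices(self.root)  # raises if the root is off-grid

    def indices(self, config: HyperConfig) -> tuple:
        """Grid coordinates of a configuration; raises if off-grid."""
        idx = []
        for name, values in self.axes.items():
            v = getattr(config, name)
            if v not in values:
                raise ValueError(f"{name}={v!r} is not on the grid {values}")
            idx.append(values.index(v))
        return tuple(idx)

    def from_indices(self, idx) -> HyperConfig:
        fields = {name: values[i] for (name, values), i in zip(self.axes.items(), idx)}
        return replace(self.root, **fields)

    def neighbors(self, config: HyperConfig) -> list[HyperConfig]:
        """Single-axis, single-step neighbours in deterministic axis order."""
        idx = self.indices(config)
        out = []
        for a, (name, values) in enumerate(self.axes.items()):
            for step in (-1, +1):
                i = idx[a] + step
                if 0 <= i < len(values):
                    out.append(self.from_indices(idx[:a] + (i,) + idx[a + 1:]))
        return out

    def all_configs(self) -> list[HyperConfig]:
        configs = [self.root]
        for name, values in self.axes.items():
            configs = [replace(c, **{name: v}) for c in configs for v in values]
        return configs

    @property
    def size(self) -> int:
        size = 1
        for values in self.axes.values():
            size *= len(values)
        return size

    def numeric_axes(self) -> dict:
        """Numeric encodings per axis for the continuous tuners.

        Booleans map to 1/0; an unbounded depth (None) is encoded as the
        axis's numeric maximum plus one.
        """
        enc = {}
        for name, values in self.axes.items():
            nums = []
            numeric_max = max(
                (float(v) for v in values if isinstance(v, (int, float)) and not isinstance(v, bool)),
                default=0.0,
            )
            for v in values:
                if v is None:
                    nums.append(numeric_max + 1.0)
                elif isinstance(v, bool):
                    nums.append(1.0 if v else 0.0)
                elif isinstance(v, (int, float)):
                    nums.append(float(v))
                else:
                    raise ValueError(f"axis {name!r} value {v!r} has no numeric encoding")
            enc[name] = nums
        return enc


def default_rf_grid() -> HyperGraph:
    """The 72-point random-forest grid used throughout the package.

    Contains both the scikit-learn default configuration (the search root)
    and the reference optimum (100 trees, depth 5, min leaf 2, bootstrap).
    """
    return HyperGraph(
        axes={
            "n_estimators": [50, 100, 200],
            "max_depth": [3, 5, 10, None],
            "min_samples_leaf": [1, 2, 4],
            "bootstrap": [True, False],
        },
        root=HyperConfig(),
    )


def bfs_tune(
    graph: HyperGraph,
    mask,
    split: SplitPair,
    cfg: BfsConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
    score_fn: Callable[[HyperConfig], float] | None = None,
) -> SearchTrace:
    """Breadth-first hyperparameter tuning over a grid graph.

    Maximizes (cross-)validation accuracy by minimizing 1 - accuracy from
    the grid root outward.  Because the root (the default configuration) is
    always evaluated first, the tuned result can never be worse than the
    default on the tuning objective.  ``score_fn`` (config -> accuracy)
    replaces model training for oracle checks.
    """
    spec = spec or ClassifierSpec()
    mask = tuple(int(b) for b in mask) if mask is not None else None
    if score_fn is not None:
        def evaluate(config):
            score = float(score_fn(config))
            return FitnessRecord(
                mask=mask or (), fitness=1.0 - score, accuracy=score, hyper=config,
            )
    else:
        def evaluate(config):
            rec = evaluate_config(config, mask, split, spec=spec, folds=folds, seed=seed)
            rec.fitness = 1.0 - rec.accuracy
            return rec

    expand = lambda c, visited: [nb for nb in graph.neighbors(c) if nb not in visited]
    return bfs_minimize(graph.root, expand, evaluate, cfg, seed=seed, algorithm="BFS")


def summarize_best_config(trace: SearchTrace) -> dict:
    """Hyperparameters of the trace's best record, in reporting order."""
    if trace.best is None:
        raise ValueError("empty trace")
    if trace.best.hyper is None:
        raise ValueError("trace carries no hyperparameter configurations")
    return trace.best.hyper.to_dict()


def all_feasible_masks(d: int) -> list[Mask]:
    """All 2^d - 1 nonempty masks, for exhaustive-oracle comparisons."""
    return [
        tuple((i >> j) & 1 for j in range(d - 1, -1, -1))
        for i in range(1, 2 ** d)
    ]
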