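"""Breadth-first searches: successor relation, traversal contract, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfsselect import (
    BfsConfig,
    HyperConfig,
    HyperGraph,
    all_feasible_masks,
    bbfs_select,
    bfs_tune,
    default_rf_grid,
    successors,
    summarize_best_config,
)
from conftest import lookup_landscape


class TestSuccessors:
    def test_full_mask_yields_all_single_removals(self):
        assert successors((1, 1, 1)) == [(0, 1, 1), (1, 0, 1), (1, 1, 0)]

    def test_infeasible_all_zero_filtered(self):
        assert successors((1, 0)) == [(1, 1)]

    def test_visited_states_excluded(self):
        assert successors((1, 0, 1), visited={(1, 1, 1)}) == [(0, 0, 1), (1, 0, 0)]

    def test_removal_only_mode_never_adds_features(self):
        assert successors((1, 0, 1), removal_only=True) == [(0, 0, 1), (1, 0, 0)]


class TestBbfsSelect:
    def test_single_feature_lattice(self):
        tr = bbfs_select(None, None, fitness_fn=lambda m: 0.5, d=1)
        assert tr.best.mask == (1,)
        assert tr.n_evaluations == 1

    def test_matches_brute_force_on_seven_masks(self):
        table = lookup_landscape(3, seed=1)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6),
                         fitness_fn=table.__getitem__, d=3)
        assert tr.best.mask == min(table, key=table.get)
        assert tr.n_evaluations == 7

    def test_exhaustive_equivalence_d6(self):
        table = lookup_landscape(6, seed=2)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6),
                         fitness_fn=table.__getitem__, d=6)
        assert tr.best.mask == min(table, key=table.get)
        assert tr.n_evaluations == 63

    def test_no_mask_evaluated_twice_and_budget_respected(self):
        table = lookup_landscape(5, seed=3)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=20),
                         fitness_fn=table.__getitem__, d=5)
        masks = [rec.mask for rec in tr.evaluations]
        assert len(masks) == len(set(masks)) == 20

    def test_level_order_distances_nondecreasing(self):
        """With an unbounded beam, states are evaluated level by level:
        Hamming distance from the all-ones root never decreases."""
        table = lookup_landscape(5, seed=4)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6),
                         fitness_fn=table.__getitem__, d=5)
        dists = [sum(b == 0 for b in rec.mask) for rec in tr.evaluations]
        # distance from (1,1,1,1,1) equals the number of cleared bits only on
        # the downward lattice; re-additions keep graph distance = Hamming
        hamming = [sum(a != b for a, b in zip(rec.mask, (1,) * 5)) for rec in tr.evaluations]
        assert hamming == sorted(hamming)
        assert dists[0] == 0

    def test_constant_landscape_keeps_root_as_best(self):
        tr = bbfs_select(None, None, BfsConfig(max_iterations=30),
                         fitness_fn=lambda m: 0.25, d=4)
        assert tr.best.mask == (1, 1, 1, 1)  # earliest evaluated wins ties
        assert tr.best_so_far == [0.25] * 15  # all 15 feasible masks visited

    def test_patience_halts_on_stalled_levels(self):
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6, patience=2),
                         fitness_fn=lambda m: 0.25, d=6)
        # root level + 2 stalled levels: 1 + 6 + evaluations of level 2 only
        assert tr.n_evaluations < 63

    def test_beam_width_bounds_level_growth(self):
        table = lookup_landscape(6, seed=5)
        tr = bbfs_select(None, None,
                         BfsConfig(max_iterations=10**6, beam_width=1, max_levels=3),
                         fitness_fn=table.__getitem__, d=6)
        # root + first level (6) + at most 6 per beam-1 level thereafter
        assert tr.n_evaluations <= 1 + 6 + 6 + 6

    def test_best_so_far_nonincreasing(self):
        table = lookup_landscape(6, seed=6)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6),
                         fitness_fn=table.__getitem__, d=6)
        assert all(a >= b for a, b in zip(tr.best_so_far, tr.best_so_far[1:]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), d=st.integers(2, 5))
    def test_oracle_equivalence_property(self, seed, d):
        table = lookup_landscape(d, seed=seed)
        tr = bbfs_select(None, None, BfsConfig(max_iterations=10**6),
                         fitness_fn=table.__getitem__, d=d)
        assert tr.best.mask == min(table, key=table.get)

    def test_real_split_selects_separating_feature(self, small_split):
        from bfsselect import ClassifierSpec

        tr = bbfs_select(small_split, ClassifierSpec(kind="NBC"),
                         BfsConfig(max_iterations=7), alpha=0.99, seed=0)
        assert tr.best.mask[0] == 1
        assert tr.best.accuracy == 1.0


class TestHyperGraph:
    def test_neighbors_differ_in_exactly_one_axis(self):
        g = default_rf_grid()
        root_idx = g.indices(g.root)
        for nb in g.neighbors(g.root):
            diff = [a != b for a, b in zip(root_idx, g.indices(nb))]
            assert sum(diff) == 1

    def test_off_grid_root_rejected(self):
        with pytest.raises(ValueError, match="not on the grid"):
            HyperGraph(axes={"n_estimators": [50, 200]}, root=HyperConfig(n_estimators=100))

    def test_default_grid_size_and_membership(self):
        g = default_rf_grid()
        assert g.size == 72
        assert len(g.all_configs()) == 72
        # the reference optimum and the library default are both grid points
        g.indices(HyperConfig(n_estimators=100, max_depth=5, min_samples_leaf=2, bootstrap=True))
        g.indices(HyperConfig())

    def test_numeric_encoding_of_none_and_bool(self):
        g = default_rf_grid()
        enc = g.numeric_axes()
        assert enc["max_depth"] == [3.0, 5.0, 10.0, 11.0]  # None -> max + 1
        assert enc["bootstrap"] == [1.0, 0.0]


class TestBfsTune:
    def test_one_axis_grid_picks_best_score(self):
        g = HyperGraph(axes={"n_estimators": [50, 100, 200]})
        scores = {50: 0.8, 100: 0.9, 200: 0.7}
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=10**6),
                      score_fn=lambda c: scores[c.n_estimators])
        assert tr.best.hyper.n_estimators == 100

    def test_unbounded_budget_matches_grid_search(self):
        g = default_rf_grid()
        rng = np.random.default_rng(0)
        vals = {tuple(c.to_dict().items()): float(v)
                for c, v in zip(g.all_configs(), rng.random(g.size))}
        score = lambda c: vals[tuple(c.to_dict().items())]
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=10**6), score_fn=score)
        assert tr.best.hyper == max(g.all_configs(), key=score)
        assert tr.n_evaluations == 72

    def test_root_global_best_keeps_flat_trace(self):
        g = HyperGraph(axes={"n_estimators": [50, 100, 200]})
        score = lambda c: 1.0 if c.n_estimators == 100 else 0.5
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=10**6), score_fn=score)
        assert tr.best_so_far == [0.0] * 3

    def test_tuned_never_worse_than_root(self, synth_split):
        from bfsselect import ClassifierSpec

        tr = bfs_tune(default_rf_grid(), (1,) * 6, synth_split,
                      BfsConfig(max_iterations=6), folds=1, seed=0,
                      spec=ClassifierSpec(kind="RF", seed=0))
        assert tr.best.fitness <= tr.evaluations[0].fitness


class TestSummarizeBestConfig:
    def test_reference_optimum_serialized_in_order(self):
        g = default_rf_grid()
        target = HyperConfig(n_estimators=100, max_depth=5, min_samples_leaf=2, bootstrap=True)
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=10**6),
                      score_fn=lambda c: 1.0 if c == target else 0.1)
        assert summarize_best_config(tr) == {
            "n_estimators": 100, "max_depth": 5, "min_samples_leaf": 2, "bootstrap": True,
        }

    def test_single_evaluation_trace(self):
        g = HyperGraph(axes={"n_estimators": [100]})
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=1), score_fn=lambda c: 0.5)
        assert summarize_best_config(tr)["n_estimators"] == 100

    def test_fitness_ties_resolved_to_earliest(self):
        g = HyperGraph(axes={"n_estimators": [50, 100, 200]})
        tr = bfs_tune(g, None, None, BfsConfig(max_iterations=10**6), score_fn=lambda c: 0.9)
        assert tr.best.hyper == g.root
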