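import numpy as np
import pytest

from bfsselect import (
    FeatureTable,
    SplitPair,
    SynthConfig,
    all_feasible_masks,
    generate_table,
    standardize,
    stratified_split,
)


@pytest.fixture
def tiny_table() -> FeatureTable:
    """12 samples, 3 features; feature 0 separates the classes perfectly."""
    rng = np.random.default_rng(7)
    labels = np.array([0, 1] * 6)
    values = np.column_stack([
        labels * 10.0 + rng.normal(0, 0.5, 12),   # separating feature
        rng.normal(0, 1, 12),                     # noise
        rng.normal(5, 2, 12),                     # noise
    ])
    return FeatureTable(values, labels, ["sep", "noise_a", "noise_b"])


@pytest.fixture
def small_split(tiny_table) -> SplitPair:
    return stratified_split(tiny_table, fraction=2 / 3, seed=0)


@pytest.fixture
def synth_split() -> SplitPair:
    """Standardized 80/20 split of a 200x6 synthetic set, 2 informative features."""
    table, _ = generate_table(
        SynthConfig(n=200, d=6, informative=(0, 2), effect_size=1.5, seed=3)
    )
    split = stratified_split(table, 0.8, seed=3)
    _, train_z, val_z = standardize(split.train, split.val)
    return SplitPair(train_z, val_z, split.fraction, split.seed,
                     split.train_idx, split.val_idx)


def lookup_landscape(d: int, seed: int):
    """A deterministic random fitness table over all feasible masks of size d."""
    rng = np.random.default_rng(seed)
    masks = all_feasible_masks(d)
    table = {m: float(v) for m, v in zip(masks, rng.random(len(masks)))}
    return table
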