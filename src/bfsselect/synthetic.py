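"""Synthetic tabular data with controllable ground truth.

Generates datasets shaped like the vertebral-column biomechanics cohort the
package targets: ~310 patients, six numeric spino-pelvic measurements
(pelvic incidence, pelvic tilt, lumbar lordosis angle, sacral slope, pelvic
radius, degree of spondylolisthesis) and a binary normal/abnormal label with
a ~0.68 positive rate.  Informative features can be planted (class means
separated by a chosen number of SDs) and cells can be masked completely at
random, so imputation and feature-recovery behaviour are testable without
any external download.

This generator is a test harness with known ground truth, not a faithful
statistical model of the real cohort: features are independent Gaussians
(optionally log-normal for the heavily skewed spondylolisthesis column) and
carry none of the real measurements' correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureTable

__all__ = ["SynthConfig", "GroundTruth", "generate_table", "inject_missing",
           "REFERENCE_FEATURES", "REFERENCE_MEANS", "REFERENCE_SDS",
           "REFERENCE_CLASS_BALANCE"]

# Summary statistics of the reference cohort's six measurements (units:
# degrees for the angles, mm for pelvic radius, % slip for spondylolisthesis).
REFERENCE_FEATURES = (
    "pelvic_incidence",
    "pelvic_tilt",
    "lumbar_lordosis_angle",
    "sacral_slope",
    "pelvic_radius",
    "degree_spondylolisthesis",
)
REFERENCE_MEANS = (60.496653, 17.542822, 51.930930, 42.953831, 117.920655, 26.296694)
REFERENCE_SDS = (17.236520, 10.008330, 18.554064, 13.423102, 13.317377, 37.559027)
REFERENCE_CLASS_BALANCE = 0.677419  # P(label = 1), i.e. the "normal" share


@dataclass
class SynthConfig:
    """Configuration of one synthetic dataset.

    ``informative`` lists 0-based feature indices whose class-conditional
    means are separated by ``effect_size`` SDs (each class shifted by
    effect_size/2 from the marginal mean).  ``missing_rate`` masks cells
    MCAR after generation.
    """

    n: int = 310
    d: int = 6
    feature_means: tuple | None = None
    feature_sds: tuple | None = None
    feature_names: tuple | None = None
    class_balance: float = REFERENCE_CLASS_BALANCE
    informative: tuple = ()
    effect_size: float = 1.0
    missing_rate: float = 0.0
    lognormal_spondylolisthesis: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.d < 1:
            raise ValueError("d must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(j < 0 or j >= self.d for j in self.informative):
            raise ValueError("informative indices must lie in [0, d)")
        if self.feature_means is None:
            self.feature_means = REFERENCE_MEANS if self.d == 6 else (0.0,) * self.d
        if self.feature_sds is None:
            self.feature_sds = REFERENCE_SDS if self.d == 6 else (1.0,) * self.d
        if self.feature_names is None:
            self.feature_names = (
                REFERENCE_FEATURES if self.d == 6
                else tuple(f"feature_{j}" for j in range(self.d))
            )
        if not (len(self.feature_means) == len(self.feature_sds)
                == len(self.feature_names) == self.d):
            raise ValueError("feature_means/feature_sds/feature_names must have length d")
        if any(s <= 0 for s in self.feature_sds):
            raise ValueError("feature_sds must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    informative: tuple
    class_means: dict = field(default_factory=dict)  # name -> (mean0, mean1)
    class_balance: float = 0.5


def generate_table(cfg: SynthConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one dataset; deterministic per ``cfg.seed``.

    Labels ~ Bernoulli(class_balance); informative features are Gaussian with
    class-dependent means mu -/+ (effect_size/2)*sd for classes 0/1;
    the rest are class-independent Gaussians.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = (rng.random(cfg.n) < cfg.class_balance).astype(int)
    # Degenerate draw: force both classes present so splits stay stratifiable.
    if labels.min() == labels.max():
        labels[rng.integers(cfg.n)] = 1 - labels[0]

    means = np.asarray(cfg.feature_means, dtype=float)
    sds = np.asarray(cfg.feature_sds, dtype=float)
    shift = np.zeros(cfg.d)
    shift[list(cfg.informative)] = cfg.effect_size / 2.0
    # class 0 at mu - shift*sd, class 1 at mu + shift*sd
    centers = means[None, :] + np.where(labels[:, None] == 1, 1.0, -1.0) * shift[None, :] * sds[None, :]
    values = rng.normal(loc=centers, scale=sds[None, :])

    if cfg.lognormal_spondylolisthesis and "degree_spondylolisthesis" in cfg.feature_names:
        j = cfg.feature_names.index("degree_spondylolisthesis")
        mu, sd = means[j], sds[j]
        # log-normal matched to the target mean/SD, then re-centred so the
        # planted class shift (if any) is preserved additively
        s2 = np.log(1.0 + (sd / mu) ** 2)
        values[:, j] = rng.lognormal(np.log(mu) - s2 / 2.0, np.sqrt(s2), cfg.n)
        values[:, j] += centers[:, j] - mu

    table = FeatureTable(values, labels, list(cfg.feature_names))
    truth = GroundTruth(
        informative=tuple(sorted(cfg.informative)),
        class_means={
            cfg.feature_names[j]: (means[j] - shift[j] * sds[j], means[j] + shift[j] * sds[j])
            for j in range(cfg.d)
        },
        class_balance=cfg.class_balance,
    )
    if cfg.missing_rate > 0:
        table = inject_missing(table, cfg.missing_rate, seed=cfg.seed + 1)
    return table, truth


def inject_missing(t: FeatureTable, rate: float, seed: int = 0) -> FeatureTable:
    """Mask each cell independently with probability ``rate`` (MCAR).

    A mask that would blank an entire row or column is redrawn, so the
    result always remains imputable.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return t.copy()
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        mask = rng.random(t.values.shape) < rate
        if not mask.all(axis=1).any() and not mask.all(axis=0).any():
            break
    else:  # pragma: no cover - essentially unreachable for rate < 1
        raise RuntimeError("could not draw a mask keeping every row/column observed")
    values = t.values.copy()
    values[mask] = np.nan
    return FeatureTable(values, t.labels.copy(), t.feature_names)
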