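"""Classifier registry, feature-subset restriction and the wrapper fitness.

The fitness of a feature subset S is the validation accuracy of a model
trained on the training part restricted to S:

    F(S) = (1/n_val) * sum_i I(yhat_i == y_i)

The searches minimize either 1 - F(S) or the size-penalized composite

    alpha * (1 - F(S)) + (1 - alpha) * |S| / d

which trades accuracy against parsimony (alpha close to 1 weights accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .preprocess import FeatureTable, SplitPair

__all__ = [
    "MODEL_KINDS",
    "HyperConfig",
    "ClassifierSpec",
    "FitnessRecord",
    "build_classifier",
    "subset_features",
    "fitness_accuracy",
    "fitness_composite",
    "evaluate_config",
]

#: The six supported model kinds: random forest, stochastic gradient descent,
#: Gaussian naive Bayes, dummy (most-frequent), quadratic discriminant
#: analysis and extra trees.
MODEL_KINDS = ("RF", "SGD", "NBC", "DC", "QDA", "ET")


@dataclass(frozen=True)
class HyperConfig:
    """One point in the random-forest hyperparameter grid.

    Defaults are the scikit-learn defaults, which also serve as the tuning
    root so a tuned configuration can never score worse than the default on
    the tuning objective.
    """

    n_estimators: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    bootstrap: bool = True

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None (unbounded)")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be positive")

    def to_dict(self) -> dict:
        """Serialize in the conventional reporting order."""
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "bootstrap": self.bootstrap,
        }


@dataclass(frozen=True)
class ClassifierSpec:
    """Which model to train, with which hyperparameters and seed."""

    kind: str = "RF"
    hyper: HyperConfig = field(default_factory=HyperConfig)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


def build_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec.

    The hyperparameter grid applies to the tree ensembles (RF/ET); the other
    four models use library defaults.  QDA and NBC are deterministic and
    ignore the seed.
    """
    h = spec.hyper
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=h.n_estimators,
            max_depth=h.max_depth,
            min_samples_leaf=h.min_samples_leaf,
            bootstrap=h.bootstrap,
            random_state=spec.seed,
        )
    if spec.kind == "ET":
        return ExtraTreesClassifier(
            n_estimators=h.n_estimators,
            max_depth=h.max_depth,
            min_samples_leaf=h.min_samples_leaf,
            bootstrap=h.bootstrap,
            random_state=spec.seed,
        )
    if spec.kind == "SGD":
        return SGDClassifier(random_state=spec.seed)
    if spec.kind == "NBC":
        return GaussianNB()
    if spec.kind == "DC":
        return DummyClassifier(strategy="most_frequent")
    if spec.kind == "QDA":
        return QuadraticDiscriminantAnalysis()
    raise ValueError(spec.kind)  # pragma: no cover - guarded in __post_init__


@dataclass
class FitnessRecord:
    """One evaluated search state.

    ``fitness`` is the minimized objective (composite or 1-accuracy for the
    tuner); ``accuracy`` is the raw validation accuracy F(S) when a real
    model was trained (None for injected test objectives).
    """

    mask: tuple
    fitness: float
    accuracy: float | None = None
    hyper: HyperConfig | None = None

    @property
    def select_ratio(self) -> float:
        return sum(self.mask) / len(self.mask) if self.mask else float("nan")


def subset_features(t: FeatureTable, mask) -> FeatureTable:
    """Restrict a table to the columns where mask = 1, order preserved."""
    mask = tuple(int(b) for b in mask)
    if len(mask) != t.d:
        raise ValueError(f"mask length {len(mask)} != feature count {t.d}")
    if set(mask) - {0, 1}:
        raise ValueError("mask must be binary")
    if sum(mask) == 0:
        raise ValueError("empty feature set is infeasible")
    cols = [j for j, b in enumerate(mask) if b]
    return FeatureTable(
        t.values[:, cols], t.labels.copy(), [t.feature_names[j] for j in cols]
    )


def fitness_accuracy(mask, split: SplitPair, spec: ClassifierSpec) -> FitnessRecord:
    """Wrapper fitness: holdout validation accuracy of feature subset S.

    Training failures (e.g. QDA with a singular class covariance) score 0
    with a warning rather than raising, so searches stay total.
    """
    mask = tuple(int(b) for b in mask)
    train = subset_features(split.train, mask)
    val = subset_features(split.val, mask)
    try:
        clf = build_classifier(spec)
        clf.fit(train.values, train.labels)
        pred = clf.predict(val.values)
        acc = float(np.mean(pred == val.labels))
    except Exception as exc:  # noqa: BLE001 - fitness must stay total
        warnings.warn(f"training failed for {spec.kind} on mask {mask}: {exc}", stacklevel=2)
        acc = 0.0
    return FitnessRecord(mask=mask, fitness=acc, accuracy=acc, hyper=spec.hyper)


def fitness_composite(rec: FitnessRecord, alpha: float = 0.99) -> float:
    """Size-penalized objective alpha*(1-acc) + (1-alpha)*|S|/d; lower is better."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if rec.accuracy is None:
        raise ValueError("record has no accuracy to penalize")
    return alpha * (1.0 - rec.accuracy) + (1.0 - alpha) * rec.select_ratio


def evaluate_config(
    hyper: HyperConfig,
    mask,
    split: SplitPair,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    seed: int = 0,
) -> FitnessRecord:
    """Score one hyperparameter configuration on a fixed feature subset.

    With ``folds == 1`` this is the plain holdout fitness; with more folds
    the accuracy is averaged over stratified k-fold cross-validation of the
    *training* part (the validation part is left untouched for the final
    comparison).  Deterministic under fixed seeds.
    """
    if folds < 1:
        raise ValueError("folds must be >= 1")
    spec = spec or ClassifierSpec()
    spec = replace(spec, hyper=hyper)
    if folds == 1:
        return fitness_accuracy(mask, split, spec)

    mask = tuple(int(b) for b in mask)
    train = subset_features(split.train, mask)
    counts = np.bincount(train.labels, minlength=2)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smaller class count {counts.min()} in training data"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(train.values, train.labels):
        try:
            clf = build_classifier(spec)
            clf.fit(train.values[tr], train.labels[tr])
            accs.append(float(np.mean(clf.predict(train.values[te]) == train.labels[te])))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"fold training failed for {spec.kind}: {exc}", stacklevel=2)
            accs.append(0.0)
    acc = float(np.mean(accs))
    return FitnessRecord(mask=mask, fitness=acc, accuracy=acc, hyper=hyper)
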