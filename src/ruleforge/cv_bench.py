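"""Leave-one-out cross-validation harness and tuning grids.

Any classifier that exposes ``fit(matrix, labels)`` and
``predict(matrix) -> labels`` can be benchmarked.  All preprocessing
(feature filtering, discretization) must happen inside ``fit`` so that
each fold is leakage-safe; the rule-model trainer refits its
discretization in every fold by construction.

Tuning enumerates a deterministic grid per method, scores each point by
the Cohen kappa of its LOOCV confusion matrix and keeps the first
maximizer in grid order.  Tuning on LOOCV scores directly is the
benchmarked (non-nested) protocol; ``tune_nested`` provides the
unbiased alternative where the grid is re-tuned inside every outer
fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from . import rule_engine
from .diagnostics import ConfusionMatrix, StudyAccuracy, confusion_from_predictions, kappa_multiclass, study_accuracy

__all__ = [
    "Trainer",
    "loocv",
    "tune",
    "tune_nested",
    "TUNING_GRIDS",
    "make_trainer",
    "RuleModelTrainer",
    "benchmark_report",
]


class Trainer(Protocol):
    """fit/predict contract consumed by the harness."""

    def fit(self, matrix: pd.DataFrame, labels: Sequence) -> "Trainer": ...

    def predict(self, matrix: pd.DataFrame) -> list[str]: ...


def loocv(
    matrix: pd.DataFrame,
    labels: Sequence,
    trainer_factory: Callable[[], Trainer],
) -> tuple[list[str], ConfusionMatrix]:
    """Leave-one-out predictions and the resulting confusion matrix.

    Fold ``i`` trains a fresh trainer on the other ``n - 1`` samples and
    predicts sample ``i``; a trainer failure aborts with the fold index.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    y = [str(v) for v in labels]
    if len(y) != n:
        raise ValueError("labels length does not match matrix")
    predictions: list[str] = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        try:
            trainer = trainer_factory()
            trainer.fit(matrix.iloc[keep], [y[j] for j in keep])
            pred = trainer.predict(matrix.iloc[[i]])
        except Exception as exc:  # noqa: BLE001 - refine with fold context
            raise RuntimeError(f"trainer failed on fold {i}: {exc}") from exc
        predictions.append(str(pred[0]))
    cm = confusion_from_predictions(y, predictions, labels=sorted(set(y)))
    return predictions, cm


def tune(
    matrix: pd.DataFrame,
    labels: Sequence,
    trainer_factory: Callable[..., Trainer],
    grid: Sequence[dict],
) -> tuple[dict, StudyAccuracy, list[float]]:
    """Select the grid point with maximal LOOCV Cohen kappa.

    Returns the winning parameters, the corresponding accuracy summary,
    and the per-point kappa trace (grid order).  Ties keep the first
    point in grid order.
    """
    if not grid:
        raise ValueError("empty tuning grid")
    best_point: dict | None = None
    best_kappa = -np.inf
    best_cm: ConfusionMatrix | None = None
    kappas: list[float] = []
    for point in grid:
        _, cm = loocv(matrix, labels, lambda: trainer_factory(**point))
        k = kappa_multiclass(cm)
        kappas.append(k)
        if k > best_kappa:
            best_kappa, best_point, best_cm = k, point, cm
    assert best_cm is not None and best_point is not None
    return best_point, study_accuracy(best_cm), kappas


def tune_nested(
    matrix: pd.DataFrame,
    labels: Sequence,
    trainer_factory: Callable[..., Trainer],
    grid: Sequence[dict],
) -> tuple[list[str], StudyAccuracy]:
    """Unbiased variant: re-tune the grid inside every outer LOOCV fold."""
    n = len(matrix)
    y = [str(v) for v in labels]
    predictions: list[str] = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        inner_X = matrix.iloc[keep]
        inner_y = [y[j] for j in keep]
        point, _, _ = tune(inner_X, inner_y, trainer_factory, grid)
        trainer = trainer_factory(**point)
        trainer.fit(inner_X, inner_y)
        predictions.append(str(trainer.predict(matrix.iloc[[i]])[0]))
    cm = confusion_from_predictions(y, predictions, labels=sorted(set(y)))
    return predictions, study_accuracy(cm)


# ---------------------------------------------------------------------------
# tuning grids (deterministic iteration order)
# ---------------------------------------------------------------------------

def _grid(**axes: Sequence) -> list[dict]:
    keys = list(axes)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(axes[k] for k in keys))]


#: Benchmark grids: rule model max error 2.5-7.5% (step 0.5%); kNN
#: neighbours 1-10; network hidden layers 0-1 x neurons 2-6 x learning
#: rate 0.25-0.75 (step 0.05); tree pruning {pessimistic, none,
#: cost-complexity} x max node impurity 0.0-0.1 (step 0.01); SVM
#: {linear, rbf} kernels x degree 1-10.
TUNING_GRIDS: dict[str, list[dict]] = {
    "llm": _grid(max_error=[round(0.025 + 0.005 * i, 3) for i in range(11)]),
    "knn": _grid(k=list(range(1, 11))),
    "ann": _grid(
        hidden_layers=[0, 1],
        neurons=list(range(2, 7)),
        learning_rate=[round(0.25 + 0.05 * i, 2) for i in range(11)],
    ),
    "dt": _grid(
        pruning=["pessimistic", "none", "cost_complexity"],
        max_impurity=[round(0.01 * i, 2) for i in range(11)],
    ),
    "svm": _grid(kernel=["linear", "rbf"], degree=list(range(1, 11))),
}


# ---------------------------------------------------------------------------
# trainer adapters
# ---------------------------------------------------------------------------

class RuleModelTrainer:
    """Adapter exposing the rule-model trainer through the contract."""

    def __init__(self, max_error: float = 0.05, max_bins: int = 4, top_k: int | None = None):
        self.max_error = max_error
        self.max_bins = max_bins
        self.top_k = top_k
        self.model: rule_engine.RuleModel | None = None

    def fit(self, matrix: pd.DataFrame, labels: Sequence) -> "RuleModelTrainer":
        self.model = rule_engine.train(
            matrix, labels, max_error=self.max_error, max_bins=self.max_bins, top_k=self.top_k
        )
        return self

    def predict(self, matrix: pd.DataFrame) -> list[str]:
        if self.model is None:
            raise RuntimeError("fit before predict")
        return rule_engine.predict_matrix(self.model, matrix)


class _SklearnTrainer:
    """Thin wrapper around an sklearn estimator, with optional scaling."""

    def __init__(self, estimator, scale: bool = False):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self.est = make_pipeline(StandardScaler(), estimator) if scale else estimator

    def fit(self, matrix: pd.DataFrame, labels: Sequence) -> "_SklearnTrainer":
        self.est.fit(matrix.to_numpy(dtype=float), [str(v) for v in labels])
        return self

    def predict(self, matrix: pd.DataFrame) -> list[str]:
        return [str(v) for v in self.est.predict(matrix.to_numpy(dtype=float))]


def make_trainer(method: str, seed: int = 0, **params) -> Trainer:
    """Instantiate a trainer for one grid point of a named method.

    Competitor internals are delegated to scikit-learn; only the grid
    shape and the fit/predict contract are owned here.  Notes on the
    mapping: a 0-hidden-layer network is a multinomial logistic model;
    "pessimistic" tree pruning (not available in scikit-learn) is
    approximated by requiring >= 2 samples per leaf, "cost_complexity"
    by a small positive ccp_alpha; kNN uses Euclidean distance on
    standardized inputs.
    """
    method = method.lower()
    if method == "llm":
        return RuleModelTrainer(**params)
    if method == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return _SklearnTrainer(KNeighborsClassifier(n_neighbors=params.get("k", 5)), scale=True)
    if method == "ann":
        layers = params.get("hidden_layers", 1)
        lr = params.get("learning_rate", 0.5)
        if layers == 0:
            from sklearn.linear_model import LogisticRegression

            return _SklearnTrainer(LogisticRegression(max_iter=1000), scale=True)
        from sklearn.neural_network import MLPClassifier

        return _SklearnTrainer(
            MLPClassifier(
                hidden_layer_sizes=(params.get("neurons", 4),) * layers,
                learning_rate_init=lr,
                max_iter=500,
                random_state=seed,
            ),
            scale=True,
        )
    if method == "dt":
        from sklearn.tree import DecisionTreeClassifier

        pruning = params.get("pruning", "none")
        kwargs: dict = {"random_state": seed}
        if pruning == "cost_complexity":
            kwargs["ccp_alpha"] = 0.01
        elif pruning == "pessimistic":
            kwargs["min_samples_leaf"] = 2
        return _SklearnTrainer(
            DecisionTreeClassifier(min_impurity_decrease=params.get("max_impurity", 0.0), **kwargs)
        )
    if method == "svm":
        from sklearn.svm import SVC

        return _SklearnTrainer(
            SVC(kernel=params.get("kernel", "linear"), degree=params.get("degree", 3)),
            scale=True,
        )
    raise ValueError(f"unknown method {method!r}")


def benchmark_report(
    matrix: pd.DataFrame,
    labels: Sequence,
    methods: Sequence[str],
    grids: dict[str, list[dict]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Method x metric accuracy table (percent) after grid tuning."""
    grids = grids or TUNING_GRIDS
    rows = {}
    for method in methods:
        grid = grids.get(method.lower())
        if not grid:
            raise ValueError(f"no tuning grid for method {method!r}")
        _, acc, _ = tune(
            matrix, labels, lambda **p: make_trainer(method, seed=seed, **p), grid
        )
        rows[method.upper()] = acc.as_percent_row()
    return pd.DataFrame(rows).T
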