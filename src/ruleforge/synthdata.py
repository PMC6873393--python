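"""Synthetic expression-like data with planted threshold rules.

Matrices mimic the shape of public microarray diagnosis sets (tens to
hundreds of samples, 2-5 classes, many uninformative features, a few
threshold-separated informative ones).  Values live on a log-intensity
scale by default (normal per feature); ``exponentiate=True`` yields
positive linear-scale intensities instead.

The generator returns the planted single-condition ground-truth rules
so recovery can be scored without any external data, and a companion
helper draws per-study (log OR, variance) tables for meta-analysis
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rule_engine import Condition, Rule

__all__ = ["PlantedSignal", "SyntheticSpec", "simulate", "make_study_set", "two_class_spec"]


@dataclass(frozen=True)
class PlantedSignal:
    """One informative feature: shifted in ``target_class`` by ``effect`` sigmas."""

    feature: int  # column index
    target_class: str
    effect: float  # location shift in units of sigma
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    class_sizes: dict[str, int]
    n_features: int
    signals: list[PlantedSignal] = field(default_factory=list)
    baseline_mean: float = 7.0
    baseline_sigma: float = 1.0
    seed: int = 0
    exponentiate: bool = False

    def __post_init__(self) -> None:
        if not self.class_sizes:
            raise ValueError("need at least one class")
        if any(n < 1 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 1")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if len({s.feature for s in self.signals}) < len(self.signals):
            raise ValueError("duplicate informative feature")
        for s in self.signals:
            if not 0 <= s.feature < self.n_features:
                raise ValueError(f"informative feature {s.feature} out of range")
            if s.target_class not in self.class_sizes:
                raise ValueError(f"unknown target class {s.target_class!r}")
        if self.baseline_sigma <= 0:
            raise ValueError("baseline sigma must be positive")


def _feature_id(j: int) -> str:
    return f"g{j + 1:05d}"


def two_class_spec(
    n_per_class: int = 20,
    n_features: int = 200,
    effect: float = 3.0,
    seed: int = 0,
    classes: tuple[str, str] = ("A", "B"),
) -> SyntheticSpec:
    """Convenience spec: one planted up-shifted feature per class."""
    return SyntheticSpec(
        class_sizes={classes[0]: n_per_class, classes[1]: n_per_class},
        n_features=n_features,
        signals=[
            PlantedSignal(feature=0, target_class=classes[0], effect=effect),
            PlantedSignal(feature=1, target_class=classes[1], effect=effect),
        ],
        seed=seed,
    )


def simulate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series, list[Rule]]:
    """Draw a dataset from a spec.

    Returns
    -------
    matrix
        Samples x features DataFrame (feature ids ``g00001`` ...),
        sample ids ``s0001`` ... grouped by class.
    labels
        Class label per sample, aligned with the matrix index.
    truth
        Planted ground-truth rules, one ``feature > threshold`` rule per
        signal with the threshold at the midpoint of the class shift.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [cls for cls, n in spec.class_sizes.items() for _ in range(n)]
    n = len(labels)
    y = pd.Series(labels, index=[f"s{i + 1:04d}" for i in range(n)], name="class")

    values = rng.normal(spec.baseline_mean, spec.baseline_sigma, size=(n, spec.n_features))
    truth: list[Rule] = []
    y_arr = np.asarray(labels)
    for sig in spec.signals:
        shift = sig.effect * sig.sigma
        in_class = y_arr == sig.target_class
        col = rng.normal(spec.baseline_mean, sig.sigma, size=n)
        col[in_class] += shift
        values[:, sig.feature] = col
        threshold = spec.baseline_mean + shift / 2.0
        truth.append(
            Rule(
                premise=[Condition(_feature_id(sig.feature), ">", (float(threshold),))],
                consequence=sig.target_class,
            )
        )
    if spec.exponentiate:
        values = np.exp2(values)
        for rule in truth:
            cond = rule.premise[0]
            rule.premise[0] = Condition(cond.feature, cond.op, (float(2.0 ** cond.thresholds[0]),))

    matrix = pd.DataFrame(
        values, index=y.index, columns=[_feature_id(j) for j in range(spec.n_features)]
    )
    return matrix, y, truth


def make_study_set(
    n_studies: int,
    sor_true: float,
    variance_range: tuple[float, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-study (log OR, variance) table around a true sOR.

    Study variances are uniform on ``variance_range`` (a degenerate
    range pins them); each study's log OR is normal with that variance
    around ``log(sor_true)``.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    lo, hi = variance_range
    if lo <= 0 or hi < lo:
        raise ValueError("variance range must be positive with low <= high")
    if sor_true <= 0:
        raise ValueError("sor_true must be positive")
    rng = np.random.default_rng(seed)
    variances = rng.uniform(lo, hi, size=n_studies)
    log_ors = rng.normal(np.log(sor_true), np.sqrt(variances))
    return pd.DataFrame(
        {
            "study": [f"study{i + 1:03d}" for i in range(n_studies)],
            "log_or": log_ors,
            "variance": variances,
        }
    )
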