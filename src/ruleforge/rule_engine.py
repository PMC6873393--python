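"""Implicant generation and threshold-rule models.

Training works per class (one-vs-rest).  Starting from an uncovered
sample's fully specific bit pattern, the premise is generalized greedily
(bits dropped to don't-care) in the order that maximizes newly covered
same-class samples while keeping the false-positive fraction within
``max_error``; a final pruning pass drops every remaining bit whose
removal still respects the bound.  Implicants are then translated to
conjunctions of threshold conditions, one condition per feature block
with a contiguous run of admitted bins.

Rule quality follows the covering/error convention: ``C(r)`` is the
fraction of the rule's own class it captures, ``E(r)`` the fraction of
the other classes it wrongly captures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .latticization import (
    DiscretizationMap,
    binarize_matrix,
    fit_discretizer,
    top_features_by_gain,
)

__all__ = [
    "Condition",
    "Rule",
    "RuleModel",
    "Prediction",
    "generate_implicants",
    "implicants_to_rules",
    "rule_quality",
    "condition_relevance",
    "variable_relevance",
    "predict",
    "flag_outlier_rules",
    "train",
]


@dataclass(frozen=True)
class Condition:
    """A single threshold condition on one feature.

    ``op`` is one of ``"<="`` (value <= t), ``">"`` (value > t) or
    ``"in"`` (interval ``a < value <= b``).
    """

    feature: str
    op: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">", "in"):
            raise ValueError(f"unknown condition op {self.op!r}")
        if self.op == "in":
            if len(self.thresholds) != 2 or not self.thresholds[0] < self.thresholds[1]:
                raise ValueError("interval condition needs thresholds (a, b) with a < b")
        elif len(self.thresholds) != 1:
            raise ValueError("threshold condition needs exactly one threshold")

    def matches(self, value: float) -> bool:
        if self.op == "<=":
            return value <= self.thresholds[0]
        if self.op == ">":
            return value > self.thresholds[0]
        a, b = self.thresholds
        return a < value <= b

    def matches_array(self, values: np.ndarray) -> np.ndarray:
        if self.op == "<=":
            return values <= self.thresholds[0]
        if self.op == ">":
            return values > self.thresholds[0]
        a, b = self.thresholds
        return (values > a) & (values <= b)


@dataclass
class Rule:
    """Conjunction of conditions with a class consequence.

    ``covering`` and ``error`` are fractions in [0, 1] computed on the
    training data (covered own-class fraction and covered
    other-class fraction, respectively).
    """

    premise: list[Condition]
    consequence: str
    covering: float = 0.0
    error: float = 0.0

    def fires(self, sample: Mapping[str, float]) -> bool:
        for cond in self.premise:
            if cond.feature not in sample:
                raise KeyError(f"sample is missing feature {cond.feature!r}")
            if not cond.matches(float(sample[cond.feature])):
                return False
        return True

    def fires_matrix(self, matrix: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(matrix), dtype=bool)
        for cond in self.premise:
            if cond.feature not in matrix.columns:
                raise KeyError(f"matrix is missing feature {cond.feature!r}")
            out &= cond.matches_array(matrix[cond.feature].to_numpy(dtype=float))
        return out

    def features(self) -> list[str]:
        return [c.feature for c in self.premise]


@dataclass
class RuleModel:
    """A trained rule-based classifier."""

    discretization: DiscretizationMap
    rules: list[Rule]
    default_class: str
    class_sizes: dict[str, int]
    uncovered: dict[str, list[int]] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_sizes)

    def rules_for(self, cls: str) -> list[Rule]:
        return [r for r in self.rules if r.consequence == cls]

    def to_json(self) -> str:
        return json.dumps(
            {
                "discretization": self.discretization.cutoffs,
                "rules": [
                    {
                        "premise": [
                            {"feature": c.feature, "op": c.op, "thresholds": list(c.thresholds)}
                            for c in r.premise
                        ],
                        "class": r.consequence,
                        "covering": r.covering,
                        "error": r.error,
                    }
                    for r in self.rules
                ],
                "default_class": self.default_class,
                "class_sizes": self.class_sizes,
                "uncovered": self.uncovered,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleModel":
        obj = json.loads(text)
        rules = [
            Rule(
                premise=[
                    Condition(d["feature"], d["op"], tuple(d["thresholds"]))
                    for d in r["premise"]
                ],
                consequence=r["class"],
                covering=r["covering"],
                error=r["error"],
            )
            for r in obj["rules"]
        ]
        return cls(
            discretization=DiscretizationMap(cutoffs=obj["discretization"]),
            rules=rules,
            default_class=obj["default_class"],
            class_sizes={k: int(v) for k, v in obj["class_sizes"].items()},
            uncovered={k: list(v) for k, v in obj.get("uncovered", {}).items()},
        )


@dataclass
class Prediction:
    label: str
    scores: dict[str, float]
    fired: list[int]  # indices into model.rules


# ---------------------------------------------------------------------------
# implicant generation
# ---------------------------------------------------------------------------

def _error_fraction(covered_neg: int, n_neg: int) -> float:
    return covered_neg / n_neg if n_neg else 0.0


def generate_implicants(
    patterns: np.ndarray,
    labels: Sequence,
    target_class,
    max_error: float,
) -> list[np.ndarray]:
    """Greedy covering of a target class by generalized bit patterns.

    Parameters
    ----------
    patterns
        Boolean array ``(n_samples, n_bits)`` of inverse only-one coded
        samples (True == bit 1).
    labels
        Class label per sample.
    target_class
        Class whose samples must be covered.
    max_error
        Admissible false-positive fraction per implicant, in [0, 0.5].

    Returns
    -------
    list of boolean masks over bits; a sample satisfies an implicant iff
    all masked bits are 1 in its pattern.  Samples of the target class
    whose fully specific pattern already violates ``max_error`` (a
    clashing other-class sample exists) are left uncovered.
    """
    patterns = np.asarray(patterns, dtype=bool)
    y = np.asarray(list(labels))
    if patterns.ndim != 2 or patterns.shape[0] != y.size:
        raise ValueError("patterns and labels are misaligned")
    if not (0.0 <= max_error <= 0.5):
        raise ValueError("max_error must lie in [0, 0.5]")
    pos = y == target_class
    if not pos.any():
        raise ValueError(f"target class {target_class!r} absent from labels")
    neg = ~pos
    n_neg = int(neg.sum())

    covered_global = np.zeros(patterns.shape[0], dtype=bool)
    implicants: list[np.ndarray] = []
    pos_idx = np.flatnonzero(pos)

    for seed in pos_idx:
        if covered_global[seed]:
            continue
        required = patterns[seed].copy()  # require every bit that is 1 in the seed
        sat = patterns[:, required].all(axis=1)
        if _error_fraction(int((sat & neg).sum()), n_neg) > max_error:
            continue  # uncoverable at this bound
        required = _generalize(patterns, required, pos, neg, n_neg, max_error)
        sat = patterns[:, required].all(axis=1) if required.any() else np.ones(len(y), bool)
        covered_global |= sat & pos
        implicants.append(required)

    return implicants


def _generalize(
    patterns: np.ndarray,
    required: np.ndarray,
    pos: np.ndarray,
    neg: np.ndarray,
    n_neg: int,
    max_error: float,
) -> np.ndarray:
    """Drop premise bits to don't-care, gain-first then full pruning.

    Phase A removes, at each step, the bit whose removal covers the most
    additional target samples (ties: lowest bit index) subject to the
    error bound.  Phase B then prunes any remaining bit that the bound
    still allows, least discriminative bits first (a bit's standalone
    discrimination is the negative-excluding minus positive-excluding
    fraction of requiring it alone), so weakly informative conditions
    are generalized away before strongly separating ones.  Both phases
    repeat to a fixpoint.
    """
    required = required.copy()
    max_neg_cov = max_error * n_neg + 1e-9

    n_pos = int(pos.sum())
    zeros = ~patterns
    neg_zero = zeros[neg].sum(axis=0) / max(n_neg, 1)
    pos_zero = zeros[pos].sum(axis=0) / max(n_pos, 1)
    solo_score = neg_zero - pos_zero  # high = requiring this bit separates well

    while True:
        changed = False

        # phase A: positive-gain removals
        while True:
            req_idx = np.flatnonzero(required)
            if req_idx.size == 0:
                break
            Z = ~patterns[:, req_idx]  # True where a required bit is 0
            s = Z.sum(axis=1)
            base = s == 0  # currently covered
            one_away = s == 1
            neg_base = int((base & neg).sum())
            gains = Z[one_away & pos].sum(axis=0)  # new positives per candidate
            neg_adds = Z[one_away & neg].sum(axis=0)
            ok = (neg_base + neg_adds) <= max_neg_cov
            candidates = np.flatnonzero(ok & (gains > 0))
            if candidates.size == 0:
                break
            j = candidates[np.argmax(gains[candidates])]
            # argmax returns the first maximum -> lowest bit index tie-break
            required[req_idx[j]] = False
            changed = True

        # phase B: prune every bit the bound still allows, least
        # discriminative first
        while True:
            pruned = False
            req_idx = np.flatnonzero(required)
            if req_idx.size == 0:
                break
            Z = ~patterns[:, req_idx]
            s = Z.sum(axis=1)
            neg_base = int(((s == 0) & neg).sum())
            neg_adds = Z[(s == 1) & neg].sum(axis=0)
            # stable sort: equal scores fall back to ascending bit index
            order = np.argsort(solo_score[req_idx], kind="stable")
            for j in order:
                if neg_base + int(neg_adds[j]) <= max_neg_cov:
                    required[req_idx[j]] = False
                    pruned = changed = True
                    break  # recompute after each removal
            if not pruned:
                break

        if not changed:
            return required


# ---------------------------------------------------------------------------
# implicants -> rules
# ---------------------------------------------------------------------------

def _runs(admitted: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, stop) with stop exclusive."""
    runs = []
    i = 0
    q = admitted.size
    while i < q:
        if admitted[i]:
            j = i
            while j < q and admitted[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _run_condition(feature: str, run: tuple[int, int], cuts: list[float], q: int) -> Condition | None:
    lo, hi = run
    if lo == 0 and hi == q:
        return None
    if lo == 0:
        return Condition(feature, "<=", (cuts[hi - 1],))
    if hi == q:
        return Condition(feature, ">", (cuts[lo - 1],))
    return Condition(feature, "in", (cuts[lo - 1], cuts[hi - 1]))


def implicants_to_rules(
    implicants: Iterable[np.ndarray],
    dmap: DiscretizationMap,
    target_class,
    matrix: pd.DataFrame | None = None,
    labels: Sequence | None = None,
) -> list[Rule]:
    """Translate bit-mask implicants into threshold rules.

    Within each feature block the *admitted* bins are those whose bit is
    don't-care; each contiguous run of admitted bins becomes one
    condition (``<=``, ``>`` or an interval).  A block whose admitted
    bins are non-contiguous is split into one rule per combination of
    runs (with a warning).  When training data are supplied, ``C(r)``
    and ``E(r)`` are attached via :func:`rule_quality`.
    """
    offsets = dmap.block_offsets
    rules: list[Rule] = []
    for mask in implicants:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != dmap.total_bits:
            raise ValueError("implicant length inconsistent with discretization map")
        per_feature: list[list[Condition | None]] = []
        split_needed = False
        for feat in dmap.features:
            q = dmap.bin_count(feat)
            block = mask[offsets[feat] : offsets[feat] + q]
            admitted = ~block
            if not admitted.any():
                raise ValueError(f"implicant admits no bin for feature {feat!r}")
            runs = _runs(admitted)
            if len(runs) > 1:
                split_needed = True
            conds = [_run_condition(feat, r, dmap.cutoffs[feat], q) for r in runs]
            per_feature.append(conds)
        if split_needed:
            warnings.warn(
                "implicant admits non-contiguous bins; splitting into one rule per contiguous run",
                stacklevel=2,
            )
        for combo in _product(per_feature):
            premise = [c for c in combo if c is not None]
            rules.append(Rule(premise=premise, consequence=str(target_class)))
    if matrix is not None and labels is not None:
        for rule in rules:
            rule.covering, rule.error = rule_quality(rule, matrix, labels, target_class)
    return rules


def _product(per_feature: list[list]) -> Iterable[tuple]:
    if not per_feature:
        yield ()
        return
    head, *tail = per_feature
    for item in head:
        for rest in _product(tail):
            yield (item, *rest)


# ---------------------------------------------------------------------------
# quality measures
# ---------------------------------------------------------------------------

def rule_quality(
    rule: Rule, matrix: pd.DataFrame, labels: Sequence, positives
) -> tuple[float, float]:
    """Covering ``C(r)`` and error ``E(r)`` of a rule on labelled data.

    ``C(r)`` = covered positives / total positives;
    ``E(r)`` = covered negatives / total negatives.  In a binary task
    these coincide with sensitivity (or specificity) and the
    false-positive fraction.  An empty premise covers everything.
    """
    if len(matrix) == 0:
        raise ValueError("empty data")
    y = np.asarray(list(labels))
    pos = y == positives
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0:
        raise ValueError(f"no samples of positive class {positives!r}")
    if n_neg == 0:
        raise ValueError("no negative samples")
    covered = rule.fires_matrix(matrix)
    return float((covered & pos).sum() / n_pos), float((covered & ~pos).sum() / n_neg)


def condition_relevance(
    rule: Rule, condition_index: int, matrix: pd.DataFrame, labels: Sequence
) -> float:
    """Relevance ``R(c) = dE(c) * C(r)`` of one condition of a rule.

    ``dE(c) = E(r') - E(r)`` where ``r'`` drops the condition; dropping
    the last condition yields the everything-covering rule (E = 1).
    Negative differences (possible for non-greedy rules) are clipped to
    0 so the downstream product form stays in [0, 1].
    """
    if not 0 <= condition_index < len(rule.premise):
        raise IndexError("condition index out of range")
    c_r, e_r = rule_quality(rule, matrix, labels, rule.consequence)
    reduced = Rule(
        premise=[c for i, c in enumerate(rule.premise) if i != condition_index],
        consequence=rule.consequence,
    )
    if reduced.premise:
        _, e_red = rule_quality(reduced, matrix, labels, rule.consequence)
    else:
        e_red = 1.0
    return max(0.0, (e_red - e_r)) * c_r


def variable_relevance(
    model: RuleModel, feature: str, matrix: pd.DataFrame, labels: Sequence
) -> float:
    """Aggregate relevance ``R_v = 1 - prod(1 - R(c))`` of one feature.

    The product runs over every condition on the feature across all
    rules of the model; a feature used by no rule scores 0.  Features
    with ``R_v <= 0.10`` are conventionally considered marginal.
    """
    if feature not in model.discretization.cutoffs:
        raise KeyError(f"feature {feature!r} unknown to the discretization")
    prod = 1.0
    for rule in model.rules:
        for i, cond in enumerate(rule.premise):
            if cond.feature == feature:
                prod *= 1.0 - condition_relevance(rule, i, matrix, labels)
    return 1.0 - prod


def flag_outlier_rules(model: RuleModel, threshold: float = 0.10) -> list[int]:
    """Indices of rules with ``C(r) * (1 - E(r)) <= threshold``.

    Such rules typically capture a handful of anomalous samples.
    """
    return [
        i for i, r in enumerate(model.rules) if r.covering * (1.0 - r.error) <= threshold
    ]


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: RuleModel, sample: Mapping[str, float]) -> Prediction:
    """Classify one sample by covering-weighted vote.

    Each fired rule contributes its covering to its class score; the
    highest score wins, ties broken by larger training class then
    lexicographic class order.  When no rule fires the default class
    (largest training class) is returned.
    """
    scores = {cls: 0.0 for cls in model.classes}
    fired: list[int] = []
    for i, rule in enumerate(model.rules):
        if rule.fires(sample):
            scores[rule.consequence] = scores.get(rule.consequence, 0.0) + rule.covering
            fired.append(i)
    if not fired or all(v == 0.0 for v in scores.values()):
        return Prediction(label=model.default_class, scores=scores, fired=fired)
    label = min(scores, key=lambda c: (-scores[c], -model.class_sizes.get(c, 0), str(c)))
    return Prediction(label=label, scores=scores, fired=fired)


def predict_matrix(model: RuleModel, matrix: pd.DataFrame) -> list[str]:
    """Vectorized prediction over a samples x features matrix."""
    n = len(matrix)
    classes = model.classes
    scores = np.zeros((n, len(classes)))
    cls_pos = {c: j for j, c in enumerate(classes)}
    any_fired = np.zeros(n, dtype=bool)
    for rule in model.rules:
        f = rule.fires_matrix(matrix)
        scores[f, cls_pos[rule.consequence]] += rule.covering
        any_fired |= f
    out: list[str] = []
    for i in range(n):
        if not any_fired[i] or scores[i].max() == 0.0:
            out.append(model.default_class)
            continue
        best = min(
            range(len(classes)),
            key=lambda j: (-scores[i, j], -model.class_sizes.get(classes[j], 0), classes[j]),
        )
        out.append(classes[best])
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    matrix: pd.DataFrame,
    labels: Sequence,
    max_error: float = 0.05,
    max_bins: int = 4,
    top_k: int | None = None,
) -> RuleModel:
    """Train a rule model: discretize, binarize, cover each class.

    Parameters
    ----------
    matrix, labels
        Training data (samples x features) with one class label per row.
    max_error
        Admissible per-rule false-positive fraction.
    max_bins
        Maximum bins per feature during discretization.
    top_k
        Optional univariate pre-filter: keep only the ``top_k`` features
        by single-split entropy gain before fitting (refit inside every
        cross-validation fold by the harness).

    Returns
    -------
    RuleModel with per-class rules sorted by descending covering, a
    default class (largest training class), and a report of training
    samples left uncovered by their class's rules.
    """
    y = np.asarray([str(v) for v in labels])
    if top_k is not None:
        keep = top_features_by_gain(matrix, y, top_k)
        matrix = matrix[keep]
    dmap = fit_discretizer(matrix, y, max_bins=max_bins)
    patterns = binarize_matrix(matrix, dmap)

    class_sizes: dict[str, int] = {}
    for cls in np.unique(y):
        class_sizes[str(cls)] = int((y == cls).sum())
    default_class = min(class_sizes, key=lambda c: (-class_sizes[c], c))

    rules: list[Rule] = []
    uncovered: dict[str, list[int]] = {}
    for cls in sorted(class_sizes):
        implicants = generate_implicants(patterns, y, cls, max_error)
        cls_rules = implicants_to_rules(implicants, dmap, cls, matrix, y)
        cls_rules.sort(key=lambda r: -r.covering)
        rules.extend(cls_rules)
        covered = np.zeros(len(y), dtype=bool)
        for r in cls_rules:
            covered |= r.fires_matrix(matrix)
        missing = np.flatnonzero((y == cls) & ~covered)
        if missing.size:
            uncovered[cls] = [int(i) for i in missing]

    return RuleModel(
        discretization=dmap,
        rules=rules,
        default_class=default_class,
        class_sizes=class_sizes,
        uncovered=uncovered,
    )
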