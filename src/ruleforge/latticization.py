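"""Supervised discretization and inverse only-one binary coding.

Each continuous feature is cut into ordered bins by greedy
entropy-minimizing midpoint selection, then every binned value is
encoded as a block of bits that are all 1 except a single 0 at the bin
position (the complement of one-hot coding).  Per-feature blocks are
concatenated so that each sample becomes one long bit string and rule
search reduces to a search over monotone Boolean patterns.

Bins are half-open on the right: ``(-inf, c1], (c1, c2], ..., (c_{q-1}, +inf)``.
A value exactly equal to a cutoff belongs to the lower bin, so rendered
rule conditions use the ``<= / >`` convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationMap",
    "BinaryPattern",
    "fit_discretizer",
    "binarize",
    "binarize_matrix",
    "top_features_by_gain",
]


@dataclass
class DiscretizationMap:
    """Ordered per-feature cutoff lists defining discretization bins.

    Parameters
    ----------
    cutoffs
        Mapping of feature id to a strictly increasing list of cutoff
        values (in the units of the input matrix).  Insertion order
        fixes the feature order used for bit-block concatenation.
    """

    cutoffs: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for feat, cuts in self.cutoffs.items():
            cuts = [float(c) for c in cuts]
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"cutoffs for feature {feat!r} are not strictly increasing")
            self.cutoffs[feat] = cuts

    @property
    def features(self) -> list[str]:
        return list(self.cutoffs)

    def bin_count(self, feature: str) -> int:
        return len(self.cutoffs[feature]) + 1

    @property
    def bin_counts(self) -> list[int]:
        return [len(c) + 1 for c in self.cutoffs.values()]

    @property
    def block_offsets(self) -> dict[str, int]:
        """Start position of each feature's bit block in the concatenated string."""
        offsets: dict[str, int] = {}
        pos = 0
        for feat in self.cutoffs:
            offsets[feat] = pos
            pos += self.bin_count(feat)
        return offsets

    @property
    def total_bits(self) -> int:
        return sum(self.bin_counts)

    def non_informative(self) -> list[str]:
        """Features with a single bin (no cutoff survived selection)."""
        return [f for f, c in self.cutoffs.items() if not c]

    def bin_index(self, feature: str, value: float) -> int:
        """Bin of ``value``; values equal to a cutoff go to the lower bin."""
        cuts = self.cutoffs[feature]
        # side="left": value == cutoff -> index of that cutoff -> lower bin
        return int(np.searchsorted(cuts, value, side="left"))

    def to_json(self) -> str:
        return json.dumps(self.cutoffs, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        return cls(cutoffs={k: list(map(float, v)) for k, v in json.loads(text).items()})


@dataclass
class BinaryPattern:
    """One sample's concatenated inverse only-one coded bit string."""

    bits: np.ndarray  # bool, True == 1
    block_offsets: dict[str, int]

    def __str__(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def bin_of(self, feature: str, dmap: DiscretizationMap) -> int:
        """Decode the bin index of a feature from the position of its 0 bit."""
        off = self.block_offsets[feature]
        block = self.bits[off : off + dmap.bin_count(feature)]
        zeros = np.flatnonzero(~block)
        if zeros.size != 1:
            raise ValueError(f"block for {feature!r} does not contain exactly one 0")
        return int(zeros[0])


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _weighted_entropies(counts: np.ndarray, n: int) -> np.ndarray:
    """Row-wise class entropy times segment weight (row total / n)."""
    tot = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=1) * (tot[:, 0] / n)


def _partition_entropy(class_prefix: np.ndarray, boundaries: Sequence[int], n: int) -> float:
    """Weighted class entropy of a partition of the sorted sample.

    ``class_prefix[i]`` holds per-class counts of the first ``i`` sorted
    samples; ``boundaries`` are the internal split positions.
    """
    edges = [0, *boundaries, n]
    segs = np.stack([class_prefix[b] - class_prefix[a] for a, b in zip(edges, edges[1:])])
    return float(_weighted_entropies(segs, n).sum())


def _class_prefix(sorted_codes: np.ndarray, n_classes: int) -> np.ndarray:
    n = sorted_codes.size
    prefix = np.zeros((n + 1, n_classes), dtype=np.int64)
    np.cumsum(np.eye(n_classes, dtype=np.int64)[sorted_codes], axis=0, out=prefix[1:])
    return prefix


def _fit_feature(values: np.ndarray, codes: np.ndarray, n_classes: int, max_bins: int) -> list[float]:
    """Greedy entropy-minimizing cutoffs for one feature.

    Candidates are midpoints between consecutive distinct sorted values;
    cutoffs are added one at a time while the weighted class entropy of
    the partition strictly decreases, up to ``max_bins - 1`` cutoffs.
    Each round scans every remaining candidate; the split position with
    the lowest resulting partition entropy wins (ties: lowest value).
    """
    n = values.size
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    sc = codes[order]
    prefix = _class_prefix(sc, n_classes)

    # candidate split positions: between distinct consecutive values
    cand = np.flatnonzero(sv[1:] > sv[:-1]) + 1
    if cand.size == 0:
        return []

    boundaries: list[int] = []
    current_h = _partition_entropy(prefix, boundaries, n)
    eps = 1e-12
    while len(boundaries) < max_bins - 1 and cand.size:
        best_h, best_pos = np.inf, None
        edges = [0, *boundaries, n]
        for a, b in zip(edges, edges[1:]):
            pos = cand[(cand > a) & (cand < b)]
            if pos.size == 0:
                continue
            seg_h = _weighted_entropies((prefix[b] - prefix[a])[None, :], n)[0]
            left = _weighted_entropies(prefix[pos] - prefix[a], n)
            right = _weighted_entropies(prefix[b] - prefix[pos], n)
            h_all = current_h - seg_h + left + right
            i = int(np.argmin(h_all))
            if h_all[i] < best_h - 1e-15:
                best_h, best_pos = float(h_all[i]), int(pos[i])
        if best_pos is None or best_h >= current_h - eps:
            break
        boundaries = sorted([*boundaries, best_pos])
        cand = cand[cand != best_pos]
        current_h = best_h

    return [float((sv[pos - 1] + sv[pos]) / 2.0) for pos in sorted(boundaries)]


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    try:
        arr = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"expression matrix contains non-numeric values: {exc}") from exc
    if arr.isna().any().any():
        bad = arr.columns[arr.isna().any()][0]
        raise ValueError(f"expression matrix contains non-numeric or missing values (feature {bad!r})")
    return arr


def fit_discretizer(
    matrix: pd.DataFrame,
    labels: Sequence,
    max_bins: int = 4,
) -> DiscretizationMap:
    """Fit per-feature cutoffs by greedy class-entropy reduction.

    Parameters
    ----------
    matrix
        Samples x features numeric matrix (columns are feature ids).
    labels
        Class label per sample (aligned with matrix rows).
    max_bins
        Maximum number of bins per feature (>= 2).  Selection stops
        earlier when no candidate midpoint reduces the weighted class
        entropy.

    Returns
    -------
    DiscretizationMap
        Cutoffs per feature, feature order matching the matrix columns.
        Constant features receive no cutoffs (bin_count 1).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples")
    y = np.asarray(list(labels))
    if len(y) != len(matrix):
        raise ValueError("labels length does not match matrix")
    classes, codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("degenerate labels: need at least 2 classes")
    if max_bins < 2:
        raise ValueError("max_bins must be >= 2")
    arr = _check_matrix(matrix)

    cuts: dict[str, list[float]] = {}
    for feat in arr.columns:
        cuts[str(feat)] = _fit_feature(arr[feat].to_numpy(dtype=float), codes, classes.size, max_bins)
    return DiscretizationMap(cutoffs=cuts)


def binarize(sample: Mapping[str, float], dmap: DiscretizationMap) -> BinaryPattern:
    """Encode one sample as its concatenated inverse only-one bit string.

    Every feature block of ``q`` bins emits ``q`` bits, all 1 except a
    0 at the bin containing the value.
    """
    bits = np.ones(dmap.total_bits, dtype=bool)
    offsets = dmap.block_offsets
    for feat in dmap.features:
        if feat not in sample:
            raise KeyError(f"sample is missing a value for feature {feat!r}")
        value = sample[feat]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"sample value for feature {feat!r} is missing/NaN")
        bits[offsets[feat] + dmap.bin_index(feat, float(value))] = False
    return BinaryPattern(bits=bits, block_offsets=offsets)


def binarize_matrix(matrix: pd.DataFrame, dmap: DiscretizationMap) -> np.ndarray:
    """Vectorized :func:`binarize` over a samples x features matrix.

    Returns a boolean array of shape ``(n_samples, total_bits)``.
    """
    missing = [f for f in dmap.features if f not in matrix.columns]
    if missing:
        raise KeyError(f"matrix is missing feature(s) {missing}")
    n = len(matrix)
    bits = np.ones((n, dmap.total_bits), dtype=bool)
    offsets = dmap.block_offsets
    for feat in dmap.features:
        values = matrix[feat].to_numpy(dtype=float)
        idx = np.searchsorted(dmap.cutoffs[feat], values, side="left")
        bits[np.arange(n), offsets[feat] + idx] = False
    return bits


def top_features_by_gain(matrix: pd.DataFrame, labels: Sequence, k: int) -> list[str]:
    """Rank features by best single-cutoff entropy gain; return the top k.

    A cheap univariate pre-filter for very wide matrices; it never
    alters fitted cutoffs, only which features are offered to the
    discretizer.
    """
    y = np.asarray(list(labels))
    classes, codes = np.unique(y, return_inverse=True)
    arr = _check_matrix(matrix)
    n = len(arr)
    gains: list[tuple[float, str]] = []
    for feat in arr.columns:
        values = arr[feat].to_numpy(dtype=float)
        order = np.argsort(values, kind="mergesort")
        sv, sc = values[order], codes[order]
        prefix = _class_prefix(sc, classes.size)
        base = _entropy(prefix[n])
        cand = np.flatnonzero(sv[1:] > sv[:-1]) + 1
        best = 0.0
        if cand.size:
            left = _weighted_entropies(prefix[cand], n)
            right = _weighted_entropies(prefix[n] - prefix[cand], n)
            best = float(base - (left + right).min())
        gains.append((best, str(feat)))
    gains.sort(key=lambda t: (-t[0], t[1]))
    return [f for _, f in gains[:k]]
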