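"""Delimited readers/writers, rule rendering and run configuration.

All formats are plain text: TSV/CSV matrices (samples in rows by
default, header of feature ids, first column the sample id), two-column
label files, JSON model files, and TSV reports.  Rendered rules follow
the ``if <cond> AND <cond> then <class>  [covering 88.3%]`` layout and
round-trip through :func:`parse_rule`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .rule_engine import Condition, Rule, RuleModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_study_table",
    "render_rule",
    "render_rules",
    "parse_rule",
    "format_percent",
    "RunConfig",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, orientation: str = "samples-in-rows") -> pd.DataFrame:
    """Read a delimited numeric matrix; transpose genes-in-rows input.

    Raises on duplicated sample/feature ids and on non-numeric cells,
    naming the offending cell.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicated row id {dup!r} in {path}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicated column id {dup!r} in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}: {frame.loc[row, col]!r}")
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0).idxmax()
        row = numeric[col].isna().idxmax()
        raise ValueError(f"missing value at row {row!r}, column {col!r}")
    numeric.index = numeric.index.astype(str)
    numeric.index.name = None
    numeric.columns = numeric.columns.astype(str)
    numeric.columns.name = None
    if orientation == "genes-in-rows":
        numeric = numeric.T
    return numeric.astype(float)


def write_expression(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    matrix.to_csv(path, sep=_sep_for(path), index_label="sample")


def read_labels(path) -> pd.Series:
    """Two-column (sample id, class) delimited file -> Series."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if frame.shape[1] != 2:
        raise ValueError(f"label file {path} must have exactly two columns")
    sample_col, class_col = frame.columns
    if frame[sample_col].duplicated().any():
        dup = frame[sample_col][frame[sample_col].duplicated()].iloc[0]
        raise ValueError(f"duplicated sample id {dup!r} in {path}")
    return pd.Series(frame[class_col].values, index=frame[sample_col].values, name="class")


def write_labels(labels: pd.Series, path) -> None:
    path = Path(path)
    frame = pd.DataFrame({"sample": labels.index.astype(str), "class": labels.values})
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_study_table(path) -> list[tuple[float, float]]:
    """Delimited (study id, log OR, variance) table -> (log OR, var) pairs."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    if frame.shape[1] < 3:
        raise ValueError(f"study table {path} needs columns: study, log odds ratio, variance")
    log_or = pd.to_numeric(frame.iloc[:, 1], errors="raise")
    var = pd.to_numeric(frame.iloc[:, 2], errors="raise")
    return list(zip(log_or.astype(float), var.astype(float)))


# ---------------------------------------------------------------------------
# rule rendering
# ---------------------------------------------------------------------------

_NEEDS_QUOTING = re.compile(r"[\s<>=\"]")


def _fmt_feature(feature: str) -> str:
    return f'"{feature}"' if _NEEDS_QUOTING.search(feature) else feature


def _fmt_number(x: float) -> str:
    return format(x, "g")


def format_percent(fraction: float) -> str:
    """Percent with one decimal, half-up: 0.8825 -> '88.3%'."""
    q = (Decimal(repr(fraction)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def _fmt_condition(cond: Condition) -> str:
    feat = _fmt_feature(cond.feature)
    if cond.op == "<=":
        return f"{feat} ≤ {_fmt_number(cond.thresholds[0])}"
    if cond.op == ">":
        return f"{feat} > {_fmt_number(cond.thresholds[0])}"
    a, b = cond.thresholds
    return f"{_fmt_number(a)} < {feat} ≤ {_fmt_number(b)}"


def render_rule(rule: Rule) -> str:
    """One human-readable line: if-AND premise, class, covering percent."""
    premise = " AND ".join(_fmt_condition(c) for c in rule.premise) or "TRUE"
    return f"if {premise} then {rule.consequence}  [covering {format_percent(rule.covering)}]"


def render_rules(model: RuleModel) -> str:
    """All rules of a model, one per line, grouped by class, with header."""
    lines = [f"# rule model: {len(model.rules)} rule(s), default class {model.default_class}"]
    for cls in model.classes:
        lines.extend(render_rule(r) for r in model.rules_for(cls))
    return "\n".join(lines) + "\n"


_RULE_RE = re.compile(r"^if (?P<premise>.+) then (?P<cls>.+?)\s+\[covering (?P<cov>[\d.]+)%\]$")
_COND_LE = re.compile(r"^(?P<feat>\"[^\"]+\"|\S+) ≤ (?P<t>-?[\d.eE+-]+)$")
_COND_GT = re.compile(r"^(?P<feat>\"[^\"]+\"|\S+) > (?P<t>-?[\d.eE+-]+)$")
_COND_IN = re.compile(r"^(?P<a>-?[\d.eE+-]+) < (?P<feat>\"[^\"]+\"|\S+) ≤ (?P<b>-?[\d.eE+-]+)$")


def _unquote(feature: str) -> str:
    return feature[1:-1] if feature.startswith('"') and feature.endswith('"') else feature


def parse_rule(line: str) -> Rule:
    """Inverse of :func:`render_rule` (covering restored at 1e-3 precision)."""
    m = _RULE_RE.match(line.strip())
    if not m:
        raise ValueError(f"unparseable rule line: {line!r}")
    premise: list[Condition] = []
    text = m.group("premise").strip()
    if text != "TRUE":
        for part in text.split(" AND "):
            part = part.strip()
            if (g := _COND_IN.match(part)) is not None:
                premise.append(
                    Condition(_unquote(g.group("feat")), "in", (float(g.group("a")), float(g.group("b"))))
                )
            elif (g := _COND_LE.match(part)) is not None:
                premise.append(Condition(_unquote(g.group("feat")), "<=", (float(g.group("t")),)))
            elif (g := _COND_GT.match(part)) is not None:
                premise.append(Condition(_unquote(g.group("feat")), ">", (float(g.group("t")),)))
            else:
                raise ValueError(f"unparseable condition: {part!r}")
    return Rule(
        premise=premise,
        consequence=m.group("cls").strip(),
        covering=float(m.group("cov")) / 100.0,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for a benchmarking run."""

    matrix: str
    labels: str
    methods: list[str] = field(default_factory=lambda: ["llm"])
    reference_class: str | None = None
    out_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.verbosity < 0:
            raise ValueError("verbosity must be non-negative")

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**obj)
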