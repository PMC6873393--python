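"""Fixed-effect summary-ROC meta-analysis of diagnostic odds ratios.

Per-study ``(log OR, variance)`` pairs are pooled by inverse-variance
weighting into a summary odds ratio ``sOR`` whose standard error is
``sqrt(1 / sum(1/var_i))``; the 95% CI is log-symmetric.  The summary
ROC curve is ``sROC(x) = x*sOR / (x*sOR + 1 - x)`` and its area has the
closed form ``sAUC = sOR/(sOR-1) - sOR*log(sOR)/(sOR-1)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SROCResult", "pool_sor", "sroc_point", "sauc", "sroc_curve"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SROCResult:
    """Pooled summary of N diagnostic studies."""

    sor: float
    stderr_log_sor: float
    ci: tuple[float, float]
    sauc: float
    sauc_ci: tuple[float, float]
    n_studies: int
    studies: list[tuple[float, float]]  # (log OR_i, var_i)

    def as_report_row(self) -> dict[str, float]:
        return {
            "sAUC": self.sauc,
            "sAUC 95%CI low": self.sauc_ci[0],
            "sAUC 95%CI high": self.sauc_ci[1],
            "sOR": self.sor,
            "sOR 95%CI low": self.ci[0],
            "sOR 95%CI high": self.ci[1],
        }


def pool_sor(studies: Iterable[tuple[float, float]]) -> SROCResult:
    """Inverse-variance pooled summary odds ratio with log-symmetric CI.

    Parameters
    ----------
    studies
        Iterable of ``(log OR_i, var_i)`` pairs with ``var_i > 0``.

    Returns
    -------
    SROCResult
        ``log(sOR)`` is the weighted mean of the study log odds ratios
        with weights ``1/var_i``; ``StdErr[log(sOR)] =
        sqrt(1/sum(1/var_i))``; ``CI = exp(log(sOR) +/- 1.96*StdErr)``.
        The sAUC CI maps the sOR CI through the closed form.
    """
    studies = [(float(l), float(v)) for l, v in studies]
    if not studies:
        raise ValueError("empty study list")
    if any(v <= 0 for _, v in studies):
        raise ValueError("all variances must be positive")
    w = np.array([1.0 / v for _, v in studies])
    log_ors = np.array([l for l, _ in studies])
    log_sor = float((w * log_ors).sum() / w.sum())
    stderr = float(math.sqrt(1.0 / w.sum()))
    lo, hi = math.exp(log_sor - _Z95 * stderr), math.exp(log_sor + _Z95 * stderr)
    sor = math.exp(log_sor)
    return SROCResult(
        sor=sor,
        stderr_log_sor=stderr,
        ci=(lo, hi),
        sauc=sauc(sor),
        sauc_ci=(sauc(lo), sauc(hi)),
        n_studies=len(studies),
        studies=studies,
    )


def sroc_point(sor: float, x: float) -> float:
    """Sensitivity of the summary ROC curve at false-positive fraction x."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if sor <= 0.0:
        raise ValueError("sOR must be positive")
    return x * sor / (x * sor + 1.0 - x)


def sauc(sor: float) -> float:
    """Closed-form area under the summary ROC curve.

    ``sAUC = sOR/(sOR-1) - sOR*log(sOR)/(sOR-1)^2``, extended through
    the removable singularity at ``sOR = 1`` (value 1/2) by a series in
    ``d = sOR - 1``:  ``sAUC = (1+d) * (1/2 - d/3 + d^2/4 - ...)``.
    """
    if sor <= 0.0:
        raise ValueError("sOR must be positive")
    d = sor - 1.0
    if abs(d) < 1e-4:
        series = 0.5 - d / 3.0 + d**2 / 4.0 - d**3 / 5.0 + d**4 / 6.0
        return (1.0 + d) * series
    return sor / d - sor * math.log(sor) / d**2


def sroc_curve(sor: float, n_points: int = 101) -> list[tuple[float, float]]:
    """(x, sROC(x)) point series for plotting, x evenly spaced on [0, 1]."""
    xs = np.linspace(0.0, 1.0, n_points)
    return [(float(x), sroc_point(sor, float(x))) for x in xs]
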