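"""Between-device agreement statistics for paired balance scores.

Given participant-aligned pairs (Equitest equilibrium index, VR estimated
equilibrium index) for one condition, this module computes:

* two-way single-measure intraclass correlations from the mean-squares
  decomposition of the n x 2 score table — *consistency* (systematic
  device offsets forgiven) and *absolute agreement* (offsets penalized);
* the Pearson correlation with a two-sided t-distribution p-value;
* Bland-Altman statistics: mean difference and limits of agreement
  mean(d) +/- 1.96 sd(d);
* the conventional interpretation bins for ICC (poor < 0.5, moderate
  0.5-0.75, good 0.75-0.9, excellent >= 0.9) and for |r| (negligible
  < 0.3, weak 0.3-0.5, moderate 0.5-0.7, strong 0.7-0.9, very strong
  >= 0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

__all__ = [
    "PairedScores",
    "AgreementResult",
    "icc",
    "pearson",
    "bland_altman",
    "interpret_icc",
    "interpret_r",
    "analyze_pairs",
]


@dataclass(frozen=True, eq=False)
class PairedScores:
    """Participant-aligned score pairs for one condition.

    ``x`` holds the reference-device scores (Equitest EI), ``y`` the
    comparison-device scores (VR eEI), in the same participant order as
    ``pids``.  Missing values are not allowed inside a pair.
    """

    pids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "pids", tuple(self.pids))
        if not (len(self.pids) == len(x) == len(y)):
            raise ValidationError("pids, x and y must be aligned")
        if len(self.pids) != len(set(self.pids)):
            raise ValidationError("duplicate participant id in pairs")
        if x.ndim != 1 or y.ndim != 1:
            raise ValidationError("scores must be one-dimensional")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("missing or non-finite value inside a pair")

    @property
    def n(self) -> int:
        return len(self.pids)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class AgreementResult:
    """All agreement statistics for one condition's score pairs."""

    n: int
    icc_absolute: float
    icc_consistency: float
    pearson_r: float
    pearson_p: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    icc_label: str
    r_label: str


def _mean_squares(pairs: PairedScores) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the n x 2 two-way table."""
    data = np.column_stack([pairs.x, pairs.y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc(pairs: PairedScores, kind: str = "absolute") -> float:
    """Two-way single-measure intraclass correlation of an n x 2 table.

    ``kind='consistency'`` is the ICC(3,1)-type coefficient
    (MSR - MSE) / (MSR + MSE); ``kind='absolute'`` the ICC(2,1)-type
    (MSR - MSE) / (MSR + MSE + (2/n)(MSC - MSE)).
    """
    if kind not in ("absolute", "consistency"):
        raise ValidationError(f"icc kind must be 'absolute' or 'consistency', got {kind!r}")
    if pairs.n < 3:
        raise InsufficientDataError(f"ICC needs at least 3 pairs, got {pairs.n}")
    msr, msc, mse = _mean_squares(pairs)
    n, k = pairs.n, 2
    denom_c = msr + (k - 1) * mse
    if denom_c == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    if kind == "consistency":
        return (msr - mse) / denom_c
    denom_a = denom_c + (k / n) * (msc - mse)
    if denom_a == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    return (msr - mse) / denom_a


def pearson(pairs: PairedScores) -> tuple[float, float]:
    """Pearson r with two-sided p from the t-distribution on n-2 df."""
    if pairs.n < 3:
        raise InsufficientDataError(f"Pearson needs at least 3 pairs, got {pairs.n}")
    if np.std(pairs.x) == 0.0 or np.std(pairs.y) == 0.0:
        raise UndefinedStatisticError("Pearson undefined for a constant variable")
    r, p = stats.pearsonr(pairs.x, pairs.y)
    return float(r), float(p)


def bland_altman(
    x: Sequence[float] | PairedScores,
    y: Sequence[float] | None = None,
    multiplier: float = 1.96,
) -> BlandAltman:
    """Mean difference (y - x) and limits of agreement mean +/- 1.96 sd.

    The standard deviation uses the n-1 denominator.  Accepts either a
    :class:`PairedScores` or two aligned sequences.
    """
    if isinstance(x, PairedScores):
        xv, yv = x.x, x.y
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValidationError("x and y must be aligned")
    if len(xv) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = yv - xv
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=mean_diff - multiplier * sd,
        loa_high=mean_diff + multiplier * sd,
    )


_ICC_BINS = (
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.9, "good"),
    (math.inf, "excellent"),
)

_R_BINS = (
    (0.3, "negligible"),
    (0.5, "weak"),
    (0.7, "moderate"),
    (0.9, "strong"),
    (math.inf, "very strong"),
)


def interpret_icc(value: float) -> str:
    """Reliability label: poor <0.5, moderate 0.5-0.75, good 0.75-0.9,
    excellent >=0.9."""
    if not math.isfinite(value):
        raise ValidationError("ICC value must be finite")
    for upper, label in _ICC_BINS:
        if value < upper:
            return label
    raise AssertionError("unreachable")


def interpret_r(value: float) -> str:
    """Correlation-magnitude label on |r|: negligible <0.3, weak 0.3-0.5,
    moderate 0.5-0.7, strong 0.7-0.9, very strong >=0.9."""
    if not math.isfinite(value):
        raise ValidationError("r value must be finite")
    mag = abs(value)
    for upper, label in _R_BINS:
        if mag < upper:
            return label
    raise AssertionError("unreachable")


def analyze_pairs(pairs: PairedScores, ba_multiplier: float = 1.96) -> AgreementResult:
    """Compute the full agreement panel for one condition."""
    icc_a = icc(pairs, "absolute")
    icc_c = icc(pairs, "consistency")
    r, p = pearson(pairs)
    ba = bland_altman(pairs, multiplier=ba_multiplier)
    return AgreementResult(
        n=pairs.n,
        icc_absolute=icc_a,
        icc_consistency=icc_c,
        pearson_r=r,
        pearson_p=p,
        ba_mean_diff=ba.mean_diff,
        ba_loa_low=ba.loa_low,
        ba_loa_high=ba.loa_high,
        icc_label=interpret_icc(icc_a),
        r_label=interpret_r(r),
    )
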