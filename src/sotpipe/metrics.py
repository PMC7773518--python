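"""Per-trial balance metrics from a preprocessed COP trace.

Four measures are computed per trial:

* **estimated equilibrium index (eEI)** — a COP-derived analogue of the
  Equitest equilibrium index.  Peak anterior and peak posterior COP
  excursions are converted to sway angles through an inverse sine over the
  estimated center-of-gravity (COG) height, taken as 56% of stature, and
  scored against a theoretical stability limit of 12.5 degrees of combined
  forward-plus-backward sway:

      eEI = 100 * (1 - (theta_ant + theta_post) / 12.5),  clamped to [0, 100]

  so zero sway scores 100 and sway at or beyond the limit scores 0.
* **95% ellipse area** — area of the chi-square prediction ellipse expected
  to contain 95% of COP samples, ``pi * chi2_{0.95}(2) * sqrt(det(S))`` with
  S the 2x2 sample covariance of (ap, ml).
* **path length** — total COP excursion, the sum of Euclidean step lengths.
* **AP DFA alpha** — detrended fluctuation analysis scaling exponent of the
  anterior-posterior channel; ~0.5 for uncorrelated sway increments, ~1.5
  for Brownian-like drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cop_io import CopTrace
from .errors import DegenerateInputError, DomainError, ValidationError

__all__ = [
    "EiParams",
    "DfaConfig",
    "BalanceMetrics",
    "sway_angles",
    "estimated_equilibrium_index",
    "ellipse_area_95",
    "path_length",
    "dfa_alpha",
    "compute_metrics",
]


@dataclass(frozen=True)
class EiParams:
    """Equilibrium-index geometry.

    theta_limit_deg : theoretical combined sway limit in degrees (12.5).
    cog_height_fraction : COG height as a fraction of stature (0.56).
    """

    theta_limit_deg: float = 12.5
    cog_height_fraction: float = 0.56

    def __post_init__(self) -> None:
        if not 0.0 < self.cog_height_fraction < 1.0:
            raise ValidationError("cog_height_fraction must lie in (0, 1)")
        if not self.theta_limit_deg > 0:
            raise ValidationError("theta_limit_deg must be > 0")


@dataclass(frozen=True)
class DfaConfig:
    """Detrended fluctuation analysis settings.

    min_box : smallest box size in samples (default 4).
    max_box_fraction : largest box as a fraction of series length (1/4).
    n_boxes : number of log-spaced box sizes (12).
    poly_order : per-box detrending polynomial order (1).
    """

    min_box: int = 4
    max_box_fraction: float = 0.25
    n_boxes: int = 12
    poly_order: int = 1

    def __post_init__(self) -> None:
        if self.min_box < self.poly_order + 2:
            raise ValidationError("min_box must be at least poly_order + 2")
        if not 0 < self.max_box_fraction <= 1:
            raise ValidationError("max_box_fraction must lie in (0, 1]")
        if self.n_boxes < 2:
            raise ValidationError("need at least 2 box sizes")


@dataclass(frozen=True)
class BalanceMetrics:
    """The four per-trial balance measures.

    ``dfa_alpha_ap`` is NaN when DFA is undefined for the trial (constant
    AP channel); all other fields are always finite.
    """

    eei: float
    ellipse_area_95: float
    path_length: float
    dfa_alpha_ap: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.eei <= 100.0:
            raise ValidationError(f"eEI {self.eei} outside [0, 100]")
        if self.ellipse_area_95 < 0 or self.path_length < 0:
            raise ValidationError("areas and lengths must be non-negative")
        if not math.isnan(self.dfa_alpha_ap) and not self.dfa_alpha_ap > 0:
            raise ValidationError("dfa_alpha_ap must be positive or NaN (missing)")


def _cog_height(height: float, params: EiParams) -> float:
    if not height > 0:
        raise ValidationError(f"height must be > 0, got {height}")
    return params.cog_height_fraction * height


def sway_angles(
    trace: CopTrace, height: float, params: EiParams | None = None
) -> tuple[float, float]:
    """Peak anterior and posterior sway angles in degrees.

    The trace must be detrended (mean-zero AP).  The anterior angle is
    ``asin(peak_anterior / h)`` and the posterior angle ``asin(|peak
    posterior| / h)`` with ``h`` the estimated COG height; a one-sided trace
    contributes zero to the side it never visits.
    """
    params = params or EiParams()
    h = _cog_height(height, params)
    ap = trace.ap
    peak_ant = max(float(ap.max()), 0.0)
    peak_post = max(-float(ap.min()), 0.0)
    if peak_ant / h >= 1.0 or peak_post / h >= 1.0:
        raise DomainError(
            f"COP excursion ({max(peak_ant, peak_post):.3f} m) reaches the "
            f"estimated COG height ({h:.3f} m); sway angle undefined"
        )
    return (
        math.degrees(math.asin(peak_ant / h)),
        math.degrees(math.asin(peak_post / h)),
    )


def estimated_equilibrium_index(
    trace: CopTrace, height: float, params: EiParams | None = None
) -> float:
    """eEI score in [0, 100] from combined peak sway angle.

    100 means no sway; combined anterior + posterior sway at or beyond
    ``theta_limit_deg`` scores 0 (clamped).
    """
    params = params or EiParams()
    theta_ant, theta_post = sway_angles(trace, height, params)
    score = 100.0 * (1.0 - (theta_ant + theta_post) / params.theta_limit_deg)
    return float(min(100.0, max(0.0, score)))


#: 0.95 quantile of chi-square with 2 df, the prediction-ellipse constant.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


def ellipse_area_95(trace: CopTrace, chi2_quantile: float = CHI2_95_2DF) -> float:
    """Area (m^2) of the 95% chi-square prediction ellipse of (ap, ml)."""
    if trace.n < 3:
        raise DegenerateInputError("ellipse area needs at least 3 samples")
    cov = np.cov(trace.ap, trace.ml, ddof=1)
    det = float(np.linalg.det(cov))
    return math.pi * chi2_quantile * math.sqrt(max(det, 0.0))


def path_length(trace: CopTrace) -> float:
    """Total COP path length (m): sum of per-step Euclidean distances."""
    if trace.n < 2:
        raise DegenerateInputError("path length needs at least 2 samples")
    return float(np.sum(np.hypot(np.diff(trace.ap), np.diff(trace.ml))))


def _box_sizes(n: int, cfg: DfaConfig) -> np.ndarray:
    max_box = int(n * cfg.max_box_fraction)
    if max_box < cfg.min_box:
        raise DegenerateInputError(
            f"series too short for DFA: max box {max_box} < min box {cfg.min_box}"
        )
    sizes = np.unique(
        np.round(
            np.exp(np.linspace(np.log(cfg.min_box), np.log(max_box), cfg.n_boxes))
        ).astype(int)
    )
    return sizes


def dfa_alpha(series: np.ndarray, cfg: DfaConfig | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent alpha.

    The mean-removed series is integrated; for each log-spaced box size the
    profile is split into non-overlapping boxes, a polynomial of
    ``poly_order`` is removed per box, and F(n) is the RMS residual over
    all covered samples.  Alpha is the least-squares slope of log F(n)
    against log n.
    """
    cfg = cfg or DfaConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("DFA input must be one-dimensional")
    n = len(x)
    if n < 4 * cfg.min_box:
        raise DegenerateInputError(
            f"DFA needs at least {4 * cfg.min_box} samples, got {n}"
        )
    profile = np.cumsum(x - x.mean())
    sizes = _box_sizes(n, cfg)
    if len(sizes) < 2:
        raise DegenerateInputError("DFA needs at least 2 distinct box sizes")

    fluct = np.empty(len(sizes))
    for i, box in enumerate(sizes):
        n_seg = n // box
        segs = profile[: n_seg * box].reshape(n_seg, box)
        t = np.arange(box, dtype=float)
        # least-squares polynomial detrend of every box at once
        coeffs = np.polynomial.polynomial.polyfit(t, segs.T, deg=cfg.poly_order)
        trend = np.polynomial.polynomial.polyval(t, coeffs)
        resid = segs - trend
        fluct[i] = np.sqrt(np.mean(resid**2))
    if np.any(fluct == 0.0):
        raise DegenerateInputError("DFA undefined: zero fluctuation at some box size")
    alpha = np.polyfit(np.log(sizes), np.log(fluct), 1)[0]
    return float(alpha)


def compute_metrics(
    trace: CopTrace,
    height: float,
    ei: EiParams | None = None,
    dfa: DfaConfig | None = None,
) -> BalanceMetrics:
    """Bundle the four per-trial measures for a preprocessed trace.

    DFA is reported as NaN (missing) when the AP channel is degenerate for
    it; the remaining measures are still computed.
    """
    ei = ei or EiParams()
    dfa = dfa or DfaConfig()
    try:
        alpha = dfa_alpha(trace.ap, dfa)
    except DegenerateInputError:
        alpha = float("nan")
    return BalanceMetrics(
        eei=estimated_equilibrium_index(trace, height, ei),
        ellipse_area_95=ellipse_area_95(trace),
        path_length=path_length(trace),
        dfa_alpha_ap=alpha,
    )
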