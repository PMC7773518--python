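"""COP signal conditioning: detrend, then moving-average filter.

The conditioning chain is fixed as detrend -> filter.  Linear detrending
removes slow drift (weight shifts, plate creep) per axis by least squares;
the moving average is a centered boxcar whose window shrinks at the trial
edges rather than padding, so no data are invented at the boundaries.

At 50 Hz a 20-ms window rounds to a single sample and the filter is the
identity; the window length stays configurable for higher-rate plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cop_io import CopTrace
from .errors import ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    ma_window_ms : moving-average window in milliseconds (default 20).
    detrend_mode : 'linear' removes a least-squares line per axis,
                   'mean' removes only the per-axis mean.
    """

    ma_window_ms: float = 20.0
    detrend_mode: str = "linear"

    def __post_init__(self) -> None:
        if not self.ma_window_ms > 0:
            raise ValidationError("ma_window_ms must be > 0")
        if self.detrend_mode not in ("linear", "mean"):
            raise ValidationError(
                f"detrend_mode must be 'linear' or 'mean', got {self.detrend_mode!r}"
            )


def detrend(trace: CopTrace, mode: str = "linear") -> CopTrace:
    """Remove the per-axis linear trend (or mean) from both COP channels."""
    if mode not in ("linear", "mean"):
        raise ValidationError(f"unknown detrend mode {mode!r}")
    kind = "linear" if mode == "linear" else "constant"
    ap = signal.detrend(trace.ap, type=kind)
    ml = signal.detrend(trace.ml, type=kind)
    # residual means are O(eps); force them to exact zero for downstream
    # peak-based statistics
    ap = ap - ap.mean()
    ml = ml - ml.mean()
    return trace.with_channels(ap, ml)


def window_samples(window_ms: float, fs: float) -> int:
    """Moving-average length in samples: max(1, round(window_ms*fs/1000))."""
    return max(1, int(round(window_ms * fs / 1000.0)))


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    n = len(x)
    half_lo = (w - 1) // 2
    half_hi = w // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def moving_average(trace: CopTrace, window_ms: float) -> CopTrace:
    """Centered moving average per axis with shrunken edge windows.

    The window covers w = max(1, round(window_ms*fs/1000)) samples; for even
    w the extra sample sits on the trailing side.  Output length equals the
    input length.
    """
    if not window_ms > 0:
        raise ValidationError("window_ms must be > 0")
    w = window_samples(window_ms, trace.fs)
    return trace.with_channels(_boxcar(trace.ap, w), _boxcar(trace.ml, w))


def preprocess(trace: CopTrace, cfg: PreprocessConfig | None = None) -> CopTrace:
    """Full conditioning chain: detrend, then moving-average filter."""
    cfg = cfg or PreprocessConfig()
    return moving_average(detrend(trace, cfg.detrend_mode), cfg.ma_window_ms)
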