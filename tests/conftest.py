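import numpy as np
import pytest

from sotpipe import CopTrace


def make_trace(ap, ml=None, fs: float = 50.0) -> CopTrace:
    """Build a CopTrace from displacement arrays with a uniform time base."""
    ap = np.asarray(ap, dtype=float)
    ml = np.zeros_like(ap) if ml is None else np.asarray(ml, dtype=float)
    t = np.arange(len(ap)) / fs
    return CopTrace(t=t, ap=ap, ml=ml, fs=fs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def random_trace(rng) -> CopTrace:
    """A 20-s, 50-Hz noise trace at realistic millimetre sway scale."""
    n = 1000
    return make_trace(rng.normal(0, 0.005, n), rng.normal(0, 0.004, n))
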