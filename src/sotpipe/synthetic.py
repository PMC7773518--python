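"""Synthetic paired Equitest/VR study generator.

The generator emulates the validation-study design — 20 participants, six
SOT conditions plus two VR-only head-tracking conditions, two devices, two
20-s trials per condition at 50 Hz — with a *tunable latent agreement*
between devices, so the whole analysis pipeline can be exercised and its
statistics checked against closed-form targets.

Score model (per participant x condition)
-----------------------------------------
A latent stability ``z ~ N(0,1)`` drives the Equitest score; the VR latent
is ``w = rho*z + sqrt(1-rho^2)*z'``, correlated with ``z`` at the planted
agreement ``rho``.  Per trial,

    EI      = clamp(m_c + s_c * z + eps,           0, 100)
    eEI_tgt = clamp(m_c + delta + s_c * w + eps',  0, 100)

with condition mean ``m_c`` (decreasing in the condition's sway scale
``sigma_c``), between-participant SD ``s_c``, trial noise SD
``noise_sd_ei`` and an optional systematic device offset ``delta``.

Each VR trial's COP trace is a mean-reverting first-order autoregressive
process whose anterior-posterior channel is then rescaled so that the
pipeline's estimated equilibrium index reproduces ``eEI_tgt`` exactly:
the drawn target's combined sway angle is solved for a scale factor of the
detrended AP channel through the same inverse-sine geometry the metric
uses.  Ignoring the rare clamp events, the two device scores are then
bivariate with equal variances ``v = s_c^2 + noise_sd_ei^2`` and
covariance ``c = rho * s_c^2``, giving the closed-form targets stored in
the truth record:

    ICC(consistency) = 2c / 2v           = rho * s_c^2 / v
    ICC(absolute)    = 2c / (2v + delta^2)
    Pearson r        = c / v             = rho * s_c^2 / v
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.signal import detrend as _sp_detrend, lfilter

from .cop_io import (
    SOT_CONDITIONS,
    VR_ONLY_CONDITIONS,
    CopTrace,
    Participant,
    Study,
    TrialRecord,
    save_study,
)
from .errors import ValidationError
from .metrics import EiParams

__all__ = [
    "SimConfig",
    "ConditionTruth",
    "TruthRecord",
    "simulate_sway_trace",
    "simulate_study",
    "write_simulated_study",
    "condition_mean_score",
]

#: Reference stature (m) used only to map sway scale to a condition mean score.
_REF_HEIGHT = 1.70

#: Nominal peak-to-SD ratio of a 20-s mean-reverting sway trace, used in the
#: same mapping.  Calibration constant, not a fitted quantity.
_PEAK_FACTOR = 2.5

#: Default per-condition stationary sway SDs (m), increasing with task
#: difficulty: a few millimetres of AP sway on a stable surface, roughly
#: a centimetre on foam.
DEFAULT_SIGMA = {
    "SOT1": 0.004,
    "SOT2": 0.005,
    "SOT3": 0.006,
    "SOT4": 0.009,
    "SOT5": 0.012,
    "SOT6": 0.011,
    "VRHT_STABLE": 0.006,
    "VRHT_FOAM": 0.011,
}

#: Default per-condition between-participant score SDs; spread widens in
#: the harder conditions.
DEFAULT_BETWEEN_SD = {
    "SOT1": 4.0,
    "SOT2": 4.0,
    "SOT3": 5.0,
    "SOT4": 7.0,
    "SOT5": 9.0,
    "SOT6": 8.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the generator.

    Heights are drawn per sex from the study demographics: mean 1.79 m
    (SD 0.079) for males, 1.66 m (SD 0.072) for females, 7 males per 20
    participants.  ``rho`` is the planted latent between-device agreement;
    ``noise_sd_ei`` the per-trial score noise of both devices, in score
    units; ``device_offset`` a systematic VR-minus-Equitest score shift.
    """

    n_participants: int = 20
    rho: float = 0.75
    noise_sd_ei: float = 3.0
    device_offset: float = 0.0
    sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    between_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    trial_seconds: float = 20.0
    fs: float = 50.0
    n_trials: int = 2
    ar_time_constant: float = 1.0
    ml_fraction: float = 0.6
    male_fraction: float = 7 / 20
    height_mean_male: float = 1.79
    height_sd_male: float = 0.03 * math.sqrt(7)
    height_mean_female: float = 1.66
    height_sd_female: float = 0.02 * math.sqrt(13)
    min_angle_deg: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [-1, 1]")
        if self.n_participants < 1:
            raise ValidationError("need at least one participant")
        if self.noise_sd_ei < 0:
            raise ValidationError("noise_sd_ei must be >= 0")
        for cond, s in self.sigma.items():
            if not s > 0:
                raise ValidationError(f"sigma[{cond!r}] must be > 0")


@dataclass(frozen=True)
class ConditionTruth:
    """Closed-form generator targets for one condition."""

    sigma: float
    mean_score: float
    between_sd: float
    noise_sd: float
    device_offset: float
    icc_consistency: float
    icc_absolute: float
    pearson_r: float


@dataclass(frozen=True)
class TruthRecord:
    """Planted parameters and the expected per-condition statistics."""

    rho: float
    conditions: dict[str, ConditionTruth]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def condition_mean_score(
    sigma: float, ei: EiParams | None = None,
    ref_height: float = _REF_HEIGHT, peak_factor: float = _PEAK_FACTOR,
) -> float:
    """Mean equilibrium-index score implied by a sway scale ``sigma``.

    A trace of stationary SD sigma typically peaks near ``peak_factor *
    sigma`` on each side; converting those nominal peaks to sway angles
    over the reference COG height and scoring them gives a condition mean
    that decreases strictly as sigma grows.
    """
    ei = ei or EiParams()
    h = ei.cog_height_fraction * ref_height
    arg = min(peak_factor * sigma / h, 0.999999)
    theta_total = 2.0 * math.degrees(math.asin(arg))
    return 100.0 * (1.0 - theta_total / ei.theta_limit_deg)


def _truth(cfg: SimConfig) -> TruthRecord:
    conditions = {}
    for cond in SOT_CONDITIONS:
        s = cfg.between_sd[cond]
        v = s**2 + cfg.noise_sd_ei**2
        c = cfg.rho * s**2
        delta = cfg.device_offset
        conditions[cond] = ConditionTruth(
            sigma=cfg.sigma[cond],
            mean_score=condition_mean_score(cfg.sigma[cond]),
            between_sd=s,
            noise_sd=cfg.noise_sd_ei,
            device_offset=delta,
            icc_consistency=c / v,
            icc_absolute=2.0 * c / (2.0 * v + delta**2),
            pearson_r=c / v,
        )
    return TruthRecord(rho=cfg.rho, conditions=conditions)


def _rng(*stream: int) -> np.random.Generator:
    """Deterministic substream generator keyed by non-negative integers."""
    return np.random.default_rng([int(abs(s)) for s in stream])


def simulate_sway_trace(
    sigma: float,
    seconds: float = 20.0,
    fs: float = 50.0,
    seed: int | np.random.Generator = 0,
    tau: float = 1.0,
    sigma_ml: float | None = None,
) -> CopTrace:
    """Mean-reverting (AR(1)) COP sway trace with stationary SD ``sigma``.

    Both axes follow x[k+1] = phi x[k] + eta with phi = exp(-1/(fs*tau)),
    started from the stationary distribution, so the series stays bounded
    over the trial and its marginal SD is sigma (AP) and ``sigma_ml``
    (ML; defaults to sigma).
    """
    if not sigma > 0:
        raise ValidationError("sigma must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(seconds * fs))
    phi = math.exp(-1.0 / (fs * tau))
    sigma_ml = sigma if sigma_ml is None else sigma_ml

    def ar(sd: float) -> np.ndarray:
        innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi**2), size=n)
        innov[0] = rng.normal(0.0, sd)  # stationary start
        # x[k] = phi x[k-1] + innov[k] as an IIR filter
        return lfilter([1.0], [1.0, -phi], innov)

    t = np.arange(n) / fs
    return CopTrace(t=t, ap=ar(sigma), ml=ar(sigma_ml), fs=fs)


def _rescale_ap_to_angle(
    ap: np.ndarray, theta_total_deg: float, cog_height: float
) -> np.ndarray:
    """Scale a detrended AP channel so its combined peak sway angle is
    exactly ``theta_total_deg`` over the given COG height."""
    peak_ant = float(ap.max())
    peak_post = float(-ap.min())
    if peak_ant <= 0 or peak_post <= 0:
        raise ValidationError("detrended AP channel must cross zero")
    theta = math.radians(theta_total_deg)

    def f(s: float) -> float:
        return (
            math.asin(s * peak_ant / cog_height)
            + math.asin(s * peak_post / cog_height)
            - theta
        )

    s_hi = cog_height * math.sin(theta) / max(peak_ant, peak_post)
    scale = brentq(f, 0.0, s_hi, xtol=1e-15, rtol=1e-15)
    return scale * ap


def _vr_trace(
    cfg: SimConfig,
    sigma: float,
    target_eei: float | None,
    height: float,
    stream: tuple[int, ...],
    ei: EiParams,
) -> CopTrace:
    raw = simulate_sway_trace(
        sigma,
        seconds=cfg.trial_seconds,
        fs=cfg.fs,
        seed=_rng(*stream),
        tau=cfg.ar_time_constant,
        sigma_ml=cfg.ml_fraction * sigma,
    )
    ap = _sp_detrend(raw.ap, type="linear")
    ap -= ap.mean()
    ml = _sp_detrend(raw.ml, type="linear")
    ml -= ml.mean()
    if target_eei is not None:
        theta_total = ei.theta_limit_deg * (1.0 - target_eei / 100.0)
        theta_total = max(theta_total, cfg.min_angle_deg)
        ap = _rescale_ap_to_angle(ap, theta_total, ei.cog_height_fraction * height)
    return raw.with_channels(ap, ml)


def simulate_study(cfg: SimConfig | None = None) -> tuple[Study, TruthRecord]:
    """Generate a full paired study plus its truth record.

    Per participant: two Equitest trials (scalar EI) for each of the six
    SOT conditions and two VR COP-trace trials for each of the six SOT
    conditions and the two VR-only head-tracking conditions — the full
    28-trial session.  Every trial draws from its own deterministic
    substream of ``cfg.seed``, so any single trial is reproducible in
    isolation.
    """
    cfg = cfg or SimConfig()
    ei_params = EiParams()
    truth = _truth(cfg)

    n_male = int(round(cfg.male_fraction * cfg.n_participants))
    participants: dict[str, Participant] = {}
    trials: list[TrialRecord] = []

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:03d}"
        sex = "M" if i < n_male else "F"
        rng_p = _rng(cfg.seed, 1, i)
        if sex == "M":
            height = rng_p.normal(cfg.height_mean_male, cfg.height_sd_male)
        else:
            height = rng_p.normal(cfg.height_mean_female, cfg.height_sd_female)
        height = float(np.clip(height, 1.40, 2.10))
        participants[pid] = Participant(pid=pid, height=height, sex=sex)

        for ci, cond in enumerate(SOT_CONDITIONS):
            m_c = truth.conditions[cond].mean_score
            s_c = cfg.between_sd[cond]
            rng_lat = _rng(cfg.seed, 2, i, ci)
            z = rng_lat.normal()
            w = cfg.rho * z + math.sqrt(1.0 - cfg.rho**2) * rng_lat.normal()

            for j in range(1, cfg.n_trials + 1):
                rng_tr = _rng(cfg.seed, 3, i, ci, j)
                ei_score = float(
                    np.clip(m_c + s_c * z + cfg.noise_sd_ei * rng_tr.normal(), 0.0, 100.0)
                )
                trials.append(
                    TrialRecord(pid, cond, "equitest", j, ei=ei_score)
                )
                target = float(
                    np.clip(
                        m_c + cfg.device_offset + s_c * w
                        + cfg.noise_sd_ei * rng_tr.normal(),
                        0.0, 100.0,
                    )
                )
                trace = _vr_trace(
                    cfg, cfg.sigma[cond], target, height,
                    (cfg.seed, 4, i, ci, j), ei_params,
                )
                trials.append(TrialRecord(pid, cond, "vr", j, trace=trace))

        for vi, cond in enumerate(VR_ONLY_CONDITIONS):
            for j in range(1, cfg.n_trials + 1):
                trace = _vr_trace(
                    cfg, cfg.sigma[cond], None, height,
                    (cfg.seed, 5, i, vi, j), ei_params,
                )
                trials.append(TrialRecord(pid, cond, "vr", j, trace=trace))

    return Study(participants=participants, trials=trials), truth


def write_simulated_study(cfg: SimConfig, outdir: str | Path) -> Path:
    """Simulate a study and write manifest, trace CSVs and truth.json."""
    study, truth = simulate_study(cfg)
    outdir = Path(outdir)
    manifest = save_study(study, outdir)
    truth.to_json(outdir / "truth.json")
    return manifest
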