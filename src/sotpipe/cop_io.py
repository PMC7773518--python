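"""Reading and writing center-of-pressure (COP) trial data.

The on-disk dialect is deliberately plain: one UTF-8 CSV per trial with a
header row naming the columns ``time`` (s), ``ap`` (anterior-posterior
displacement, anterior positive) and ``ml`` (medial-lateral displacement),
plus a YAML study manifest listing participants and trial records.  COP
displacements are stored in metres by default; a manifest may declare
``units: cm`` or ``units: mm`` and values are converted on load.  Force-plate
exports in centimetres are common, and keeping the in-memory unit fixed at
metres guarantees the inverse-sine sway-angle computation downstream never
receives an argument on the wrong scale.

All trial payloads end up in a :class:`Study` container: a mapping of
participants plus a list of :class:`TrialRecord` objects, one per trial,
where virtual-reality (``vr``) trials carry a :class:`CopTrace` and
``equitest`` trials carry the device's scalar equilibrium index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateInputError,
    FormatError,
    SamplingError,
    ValidationError,
)

#: SOT condition codes in protocol order.
SOT_CONDITIONS: tuple[str, ...] = ("SOT1", "SOT2", "SOT3", "SOT4", "SOT5", "SOT6")

#: VR-only conditions (head-rotation-only tracking on stable and foam
#: surfaces).  They complete the 28-trial session design but have no
#: Equitest counterpart and are ignored by the agreement analysis.
VR_ONLY_CONDITIONS: tuple[str, ...] = ("VRHT_STABLE", "VRHT_FOAM")

KNOWN_CONDITIONS: tuple[str, ...] = SOT_CONDITIONS + VR_ONLY_CONDITIONS

DEVICES: tuple[str, ...] = ("equitest", "vr")

_UNIT_SCALE = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}

#: Maximum tolerated deviation of any time step from 1/fs, in seconds.
UNIFORMITY_TOL = 1e-6


@dataclass(frozen=True, eq=False)
class CopTrace:
    """One trial's COP time series.

    Parameters
    ----------
    t : array-like
        Sample times in seconds, strictly increasing and uniform.
    ap : array-like
        Anterior-posterior COP displacement in metres, anterior positive.
    ml : array-like
        Medial-lateral COP displacement in metres.
    fs : float
        Sampling rate in Hz; must agree with the time stamps to within
        ``UNIFORMITY_TOL`` seconds per step.
    """

    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "fs", float(self.fs))
        if t.ndim != 1 or ap.ndim != 1 or ml.ndim != 1:
            raise ValidationError("t, ap, ml must be one-dimensional")
        if not (len(t) == len(ap) == len(ml)):
            raise ValidationError(
                f"length mismatch: t={len(t)}, ap={len(ap)}, ml={len(ml)}"
            )
        if len(t) < 2:
            raise DegenerateInputError("a COP trace needs at least 2 samples")
        if not (np.isfinite(t).all() and np.isfinite(ap).all() and np.isfinite(ml).all()):
            raise ValidationError("non-finite sample in COP trace")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError("time stamps must be strictly increasing")
        dev = np.max(np.abs(dt - 1.0 / self.fs))
        if dev >= UNIFORMITY_TOL:
            raise SamplingError(
                f"non-uniform sampling: max |dt - 1/fs| = {dev:.3g} s "
                f"exceeds {UNIFORMITY_TOL:g} s"
            )

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first time stamp)."""
        return float(self.t[-1] - self.t[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopTrace):
            return NotImplemented
        return (
            self.fs == other.fs
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.ap, other.ap)
            and np.array_equal(self.ml, other.ml)
        )

    def allclose(self, other: "CopTrace", atol: float = 1e-9) -> bool:
        """True if every sample agrees within ``atol`` and fs matches."""
        return (
            math.isclose(self.fs, other.fs, rel_tol=0, abs_tol=atol)
            and np.allclose(self.t, other.t, rtol=0, atol=atol)
            and np.allclose(self.ap, other.ap, rtol=0, atol=atol)
            and np.allclose(self.ml, other.ml, rtol=0, atol=atol)
        )

    def with_channels(self, ap: np.ndarray, ml: np.ndarray) -> "CopTrace":
        """Copy of this trace with replaced displacement channels."""
        return CopTrace(t=self.t.copy(), ap=ap, ml=ml, fs=self.fs)


@dataclass(frozen=True)
class Participant:
    """A study participant; height feeds the COG-height estimate."""

    pid: str
    height: float
    mass: float | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.height) or not (0.5 < self.height < 2.5):
            raise ValidationError(
                f"participant {self.pid!r}: height {self.height} m outside (0.5, 2.5)"
            )
        if self.mass is not None and not self.mass > 0:
            raise ValidationError(f"participant {self.pid!r}: mass must be > 0")


@dataclass(frozen=True, eq=False)
class TrialRecord:
    """One trial: a VR COP trace or an Equitest equilibrium-index score.

    ``device='vr'`` records carry ``trace``; ``device='equitest'`` records
    carry ``ei``, the scalar equilibrium index in [0, 100].
    """

    pid: str
    condition: str
    device: str
    trial_index: int
    trace: CopTrace | None = None
    ei: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in KNOWN_CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.device not in DEVICES:
            raise ValidationError(f"unknown device {self.device!r}")
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based")
        if self.device == "vr":
            if self.trace is None or self.ei is not None:
                raise ValidationError("vr trials carry a CopTrace and no EI")
        else:
            if self.ei is None or self.trace is not None:
                raise ValidationError("equitest trials carry an EI and no trace")
            if not (math.isfinite(self.ei) and 0.0 <= self.ei <= 100.0):
                raise ValidationError(f"EI {self.ei} outside [0, 100]")
            if self.condition not in SOT_CONDITIONS:
                raise ValidationError(
                    f"equitest trials only exist for SOT conditions, got {self.condition!r}"
                )

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.pid, self.condition, self.device, self.trial_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecord):
            return NotImplemented
        return self.key == other.key and self.ei == other.ei and (
            self.trace == other.trace
        )


@dataclass
class Study:
    """Container for a full paired-device study.

    Invariants: every trial's participant id exists in ``participants`` and
    the (pid, condition, device, trial_index) key is unique.  Trials are
    stored sorted by key so two studies built from differently ordered
    manifests compare equal.
    """

    participants: dict[str, Participant] = field(default_factory=dict)
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trials = sorted(self.trials, key=lambda tr: tr.key)
        seen: set[tuple] = set()
        for tr in self.trials:
            if tr.pid not in self.participants:
                raise ValidationError(f"trial references unknown participant {tr.pid!r}")
            if tr.key in seen:
                raise ValidationError(f"duplicate trial key {tr.key}")
            seen.add(tr.key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Study):
            return NotImplemented
        return self.participants == other.participants and self.trials == other.trials

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_for(
        self, pid: str | None = None, condition: str | None = None,
        device: str | None = None,
    ) -> list[TrialRecord]:
        """Trials filtered by any subset of (pid, condition, device)."""
        return [
            tr for tr in self.trials
            if (pid is None or tr.pid == pid)
            and (condition is None or tr.condition == condition)
            and (device is None or tr.device == device)
        ]


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {"time": "time", "t": "time", "ap": "ap", "ml": "ml"}


def read_trace(
    path: str | Path,
    fs_hint: float | None = None,
    unit: str = "m",
    ap_positive: str = "anterior",
) -> CopTrace:
    """Read one trial's COP trace from CSV.

    The file must have a header naming columns ``time``, ``ap`` and ``ml``
    (case-insensitive; ``t`` is accepted for ``time``).  ``unit`` rescales
    the displacement columns to metres and ``ap_positive='posterior'`` flips
    the AP sign so anterior is positive in memory.  When ``fs_hint`` is
    absent the sampling rate is the reciprocal of the median time step.
    """
    path = Path(path)
    if unit not in _UNIT_SCALE:
        raise FormatError(f"unknown displacement unit {unit!r}")
    if ap_positive not in ("anterior", "posterior"):
        raise FormatError(f"ap_positive must be 'anterior' or 'posterior', got {ap_positive!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DegenerateInputError(f"{path}: empty trace file") from exc
    cols = {}
    for c in df.columns:
        name = _COLUMN_ALIASES.get(str(c).strip().lower())
        if name is not None and name not in cols:
            cols[name] = c
    missing = {"time", "ap", "ml"} - set(cols)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) < 2:
        raise DegenerateInputError(f"{path}: a COP trace needs at least 2 rows")
    t = df[cols["time"]].to_numpy(dtype=float)
    scale = _UNIT_SCALE[unit]
    sign = -1.0 if ap_positive == "posterior" else 1.0
    ap = sign * scale * df[cols["ap"]].to_numpy(dtype=float)
    ml = scale * df[cols["ml"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"{path}: non-finite time stamp")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time stamps must be strictly increasing")
    fs = float(fs_hint) if fs_hint is not None else 1.0 / float(np.median(dt))
    return CopTrace(t=t, ap=ap, ml=ml, fs=fs)


def write_trace(trace: CopTrace, path: str | Path) -> Path:
    """Write a trace as CSV, re-readable to at least 1e-9 absolute.

    Values are printed with 12 significant digits, comfortably beyond the
    declared 1e-9 round-trip precision for metre-scale data.
    """
    path = Path(path)
    df = pd.DataFrame({"time": trace.t, "ap": trace.ap, "ml": trace.ml})
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write trace to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# study manifest
# ---------------------------------------------------------------------------


def load_study(manifest: str | Path) -> Study:
    """Load a study from a YAML manifest.

    The manifest holds global keys (``units``, ``ap_positive``), a
    ``participants`` list (pid, height [m], optional mass/sex/age) and a
    ``trials`` list.  Each trial names pid, condition, device and
    trial_index and either a ``trace`` path (relative to the manifest) for
    VR trials or an ``ei`` scalar for Equitest trials.
    """
    manifest = Path(manifest)
    try:
        doc = yaml.safe_load(manifest.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{manifest}: malformed YAML: {exc}") from exc
    if doc is None:
        return Study()
    if not isinstance(doc, Mapping):
        raise FormatError(f"{manifest}: manifest must be a mapping")
    unit = str(doc.get("units", "m"))
    ap_positive = str(doc.get("ap_positive", "anterior"))
    base = manifest.parent

    participants: dict[str, Participant] = {}
    for entry in doc.get("participants", []) or []:
        try:
            p = Participant(
                pid=str(entry["pid"]),
                height=float(entry["height"]),
                mass=float(entry["mass"]) if entry.get("mass") is not None else None,
                sex=entry.get("sex"),
                age=float(entry["age"]) if entry.get("age") is not None else None,
            )
        except KeyError as exc:
            raise FormatError(f"{manifest}: participant entry missing {exc}") from exc
        if p.pid in participants:
            raise FormatError(f"{manifest}: duplicate participant {p.pid!r}")
        participants[p.pid] = p

    trials: list[TrialRecord] = []
    for entry in doc.get("trials", []) or []:
        try:
            pid = str(entry["pid"])
            condition = str(entry["condition"])
            device = str(entry["device"])
            trial_index = int(entry["trial_index"])
        except KeyError as exc:
            raise FormatError(f"{manifest}: trial entry missing {exc}") from exc
        if pid not in participants:
            raise ValidationError(f"{manifest}: trial references unknown participant {pid!r}")
        if device == "vr":
            if "trace" not in entry:
                raise FormatError(f"{manifest}: vr trial for {pid!r} lacks a trace path")
            trace = read_trace(
                base / entry["trace"], fs_hint=entry.get("fs"),
                unit=unit, ap_positive=ap_positive,
            )
            trials.append(TrialRecord(pid, condition, device, trial_index, trace=trace))
        elif device == "equitest":
            if "ei" not in entry:
                raise FormatError(f"{manifest}: equitest trial for {pid!r} lacks an ei value")
            trials.append(
                TrialRecord(pid, condition, device, trial_index, ei=float(entry["ei"]))
            )
        else:
            raise ValidationError(f"{manifest}: unknown device {device!r}")

    return Study(participants=participants, trials=trials)


def save_study(study: Study, outdir: str | Path, traces_subdir: str = "traces") -> Path:
    """Write a study as a manifest plus one trace CSV per VR trial.

    Returns the manifest path.  ``load_study`` on the result reproduces the
    study to the trace round-trip precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tdir = outdir / traces_subdir
    tdir.mkdir(exist_ok=True)

    pdocs = []
    for p in sorted(study.participants.values(), key=lambda p: p.pid):
        d: dict = {"pid": p.pid, "height": round(p.height, 6)}
        if p.mass is not None:
            d["mass"] = round(p.mass, 3)
        if p.sex is not None:
            d["sex"] = p.sex
        if p.age is not None:
            d["age"] = p.age
        pdocs.append(d)

    tdocs = []
    for tr in study.trials:
        d = {
            "pid": tr.pid, "condition": tr.condition,
            "device": tr.device, "trial_index": tr.trial_index,
        }
        if tr.device == "vr":
            fname = f"{tr.pid}_{tr.condition}_vr_{tr.trial_index}.csv"
            write_trace(tr.trace, tdir / fname)
            d["trace"] = f"{traces_subdir}/{fname}"
            d["fs"] = tr.trace.fs
        else:
            d["ei"] = round(float(tr.ei), 6)
        tdocs.append(d)

    manifest = outdir / "manifest.yaml"
    manifest.write_text(
        yaml.safe_dump(
            {"units": "m", "ap_positive": "anterior",
             "participants": pdocs, "trials": tdocs},
            sort_keys=False,
        )
    )
    return manifest
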