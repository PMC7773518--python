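"""The six-condition SOT taxonomy and its VR counterparts.

Each sensory organization test condition degrades a specific subset of the
three balance-relevant senses.  Vision is *accurate* (eyes open, stable
surround), *inaccurate* (sway- or head-referenced surround that moves with
the participant) or *absent* (eyes closed / blacked-out headset);
somatosensation is *accurate* on a stable surface and *inaccurate* on a
sway-referenced or foam surface; vestibular input is always accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cop_io import SOT_CONDITIONS
from .errors import ValidationError

ACCURATE = "accurate"
INACCURATE = "inaccurate"
ABSENT = "absent"


@dataclass(frozen=True)
class ConditionSpec:
    """One SOT condition: labels plus per-sense information quality."""

    code: str
    equitest_desc: str
    vr_desc: str
    visual: str
    somatosensory: str
    vestibular: str = ACCURATE

    def __post_init__(self) -> None:
        if self.code not in SOT_CONDITIONS:
            raise ValidationError(f"unknown SOT condition code {self.code!r}")
        for sense in (self.visual, self.somatosensory, self.vestibular):
            if sense not in (ACCURATE, INACCURATE, ABSENT):
                raise ValidationError(f"unknown information quality {sense!r}")


CONDITIONS: dict[str, ConditionSpec] = {
    spec.code: spec
    for spec in (
        ConditionSpec(
            "SOT1",
            "Eyes opened on a stable surface",
            "Stable virtual surround on a stable surface",
            visual=ACCURATE, somatosensory=ACCURATE,
        ),
        ConditionSpec(
            "SOT2",
            "Eyes closed on a stable surface",
            "Blacked out environment on a stable surface",
            visual=ABSENT, somatosensory=ACCURATE,
        ),
        ConditionSpec(
            "SOT3",
            "Eyes opened with a sway-referenced surround",
            "Head-referenced virtual surround on a stable surface",
            visual=INACCURATE, somatosensory=ACCURATE,
        ),
        ConditionSpec(
            "SOT4",
            "Eyes opened on a sway-referenced surface",
            "Stable virtual surround on a foam surface",
            visual=ACCURATE, somatosensory=INACCURATE,
        ),
        ConditionSpec(
            "SOT5",
            "Eyes closed on a sway-referenced surface",
            "Blacked out environment on a foam surface",
            visual=ABSENT, somatosensory=INACCURATE,
        ),
        ConditionSpec(
            "SOT6",
            "Eyes opened with a sway-referenced surround and on a sway-referenced surface",
            "Head-referenced virtual surround on a foam surface",
            visual=INACCURATE, somatosensory=INACCURATE,
        ),
    )
}

#: Conditions whose VR variant uses the foam (degraded-somatosensation) surface.
FOAM_CONDITIONS: tuple[str, ...] = ("SOT4", "SOT5", "SOT6")
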