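"""ISNCSCI score handling: normalization below the NLI and delta scores.

The ISNCSCI exam scores 10 key muscles per side (0–5 each, motor maximum 50
per side) and 28 dermatomes per side for light touch and pinprick (0–2 each,
sensory maximum 56 per side per modality). To compare impairment across
patients with different neurological levels of injury (NLI), scores are
normalized by dividing by the maximum attainable score over the segments
*strictly below* the NLI. Recovery between two timepoints is expressed as
raw score differences (deltas), which need no normalization since the
injury level is differenced out.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MOTOR_SEGMENTS",
    "SENSORY_SEGMENTS",
    "SEGMENT_ORDER",
    "ClinicalRecord",
    "ClinicalError",
    "normalize_below_nli",
    "max_score_below_nli",
    "delta_scores",
]

TIMEPOINTS = ("baseline", "month1", "month6")
MODALITIES = ("motor", "light_touch", "pinprick")

#: Rostral-to-caudal order of all spinal segment labels used by the exam.
SEGMENT_ORDER: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1", "S2", "S3", "S4_5",
)

#: The 10 key muscles scored per side (0-5 points each).
MOTOR_SEGMENTS: tuple[str, ...] = ("C5", "C6", "C7", "C8", "T1", "L2", "L3", "L4", "L5", "S1")

#: The 28 dermatomes scored per side per sensory modality (0-2 points each).
SENSORY_SEGMENTS: tuple[str, ...] = tuple(s for s in SEGMENT_ORDER if s != "C1")

_POINTS_PER_SEGMENT = {"motor": 5, "light_touch": 2, "pinprick": 2}
_SEGMENTS_OF = {
    "motor": MOTOR_SEGMENTS,
    "light_touch": SENSORY_SEGMENTS,
    "pinprick": SENSORY_SEGMENTS,
}


class ClinicalError(ValueError):
    """Invalid clinical score input."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's exam at one timepoint, with demographics."""

    patient_id: str
    timepoint: str
    motor_left: int
    motor_right: int
    lt_left: int
    lt_right: int
    pp_left: int
    pp_right: int
    nli: str
    ais: str
    age: float
    sex: str
    center: str

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ClinicalError(f"unknown timepoint {self.timepoint!r}")
        for name in ("motor_left", "motor_right", "lt_left", "lt_right", "pp_left", "pp_right"):
            if getattr(self, name) < 0:
                raise ClinicalError(f"{name} must be >= 0")
        if self.motor_left > 50 or self.motor_right > 50:
            raise ClinicalError("one-sided motor score cannot exceed 50")
        for name in ("lt_left", "lt_right", "pp_left", "pp_right"):
            if getattr(self, name) > 56:
                raise ClinicalError(f"one-sided sensory score {name} cannot exceed 56")


def normalize_below_nli(score: int, max_below_nli: int) -> float:
    """Score divided by the maximum attainable below the NLI, in [0, 1]."""
    if max_below_nli <= 0:
        raise ClinicalError("NLI leaves no testable segments (max score below NLI is 0)")
    if not (0 <= score <= max_below_nli):
        raise ClinicalError(f"score {score} outside [0, {max_below_nli}]")
    return score / max_below_nli


def max_score_below_nli(nli: str, modality: str, side: str = "left") -> int:
    """Maximum one-sided score over segments strictly below the NLI.

    Motor counts 5 points per key muscle below the NLI; light touch and
    pinprick count 2 points per dermatome. ``side`` is accepted for
    interface symmetry — the maxima are side-independent.
    """
    if modality not in _SEGMENTS_OF:
        raise ClinicalError(f"unknown modality {modality!r} (expected one of {MODALITIES})")
    if side not in ("left", "right"):
        raise ClinicalError(f"unknown side {side!r}")
    if nli not in SEGMENT_ORDER:
        raise ClinicalError(f"unknown neurological level {nli!r}")
    nli_pos = SEGMENT_ORDER.index(nli)
    below = [s for s in _SEGMENTS_OF[modality] if SEGMENT_ORDER.index(s) > nli_pos]
    if not below:
        raise ClinicalError(f"no scored {modality} segments below NLI {nli}")
    return _POINTS_PER_SEGMENT[modality] * len(below)


def delta_scores(rec1: ClinicalRecord, rec6: ClinicalRecord) -> dict[str, dict[str, int]]:
    """Raw score changes (later minus earlier) per modality and side."""
    if rec1.patient_id != rec6.patient_id:
        raise ClinicalError(
            f"records belong to different patients: {rec1.patient_id!r} vs {rec6.patient_id!r}"
        )
    return {
        "motor": {
            "left": rec6.motor_left - rec1.motor_left,
            "right": rec6.motor_right - rec1.motor_right,
        },
        "light_touch": {
            "left": rec6.lt_left - rec1.lt_left,
            "right": rec6.lt_right - rec1.lt_right,
        },
        "pinprick": {
            "left": rec6.pp_left - rec1.pp_left,
            "right": rec6.pp_right - rec1.pp_right,
        },
    }
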