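"""Double-polar spatial domain and stimulus–response trial records.

The frontal hemifield is described in double-polar coordinates: azimuth is
the angle away from the midsagittal plane (positive rightward), elevation the
angle away from the horizontal plane (positive upward).  In this system the
two angles are not independent — any physical direction in the frontal
hemifield satisfies ``|azimuth| + |elevation| <= 90`` (a diamond-shaped
boundary when plotted on a Cartesian azimuth–elevation grid).

All angles are in degrees at every interface; no radians leak out.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Phase",
    "Condition",
    "StimulusType",
    "DoublePolarDirection",
    "TrialRecord",
    "Violation",
    "ValidationReport",
    "validate_trials",
    "TRAINING_AZIMUTHS_DEG",
]

#: The ten feedback-training loudspeaker azimuths (deg), all at 0 elevation.
TRAINING_AZIMUTHS_DEG: tuple[float, ...] = (
    -60.0, -48.0, -36.0, -24.0, -12.0, 12.0, 24.0, 36.0, 48.0, 60.0,
)

# Sanity bounds on free-field level; experiments use 45-70 dBA.
LEVEL_DBA_MIN = 30.0
LEVEL_DBA_MAX = 90.0


class Phase(enum.Enum):
    """Session phase within the two-day plugging/training protocol."""

    CONTROL = "control"
    PRE = "pre"
    TRAINING = "training"
    POST = "post"
    POST_UNPLUGGED = "post_unplugged"


class Condition(enum.Enum):
    """Hearing condition: both ears free, or one ear plugged (+ muff)."""

    BINAURAL = "binaural"
    PLUGGED = "plugged"


class StimulusType(enum.Enum):
    """Noise-burst passband: broadband, low-pass (<1.5 kHz), high-pass (>3 kHz)."""

    BB = "BB"
    LP = "LP"
    HP = "HP"


def _round_rim(x: float) -> float:
    # kill float jitter right at the 90-deg rim before the <= comparison
    return round(x, 9)


@dataclass(frozen=True)
class DoublePolarDirection:
    """A direction in double-polar coordinates (degrees)."""

    azimuth_deg: float
    elevation_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.azimuth_deg) and math.isfinite(self.elevation_deg)):
            raise ValueError(
                f"direction angles must be finite, got "
                f"({self.azimuth_deg}, {self.elevation_deg})"
            )

    @property
    def eccentricity_deg(self) -> float:
        """|azimuth| + |elevation| — the double-polar diamond radius."""
        return abs(self.azimuth_deg) + abs(self.elevation_deg)

    def within_frontal_hemifield(self) -> bool:
        """True iff |azimuth| + |elevation| <= 90 deg (after rim rounding)."""
        return _round_rim(self.eccentricity_deg) <= 90.0


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus–response trial.

    ``reaction_time_ms`` is ``None`` when no head saccade latency is
    available; it is never encoded as 0.
    """

    trial_index: int
    phase: Phase
    condition: Condition
    stimulus_type: StimulusType
    level_dBA: float
    target: DoublePolarDirection
    response: DoublePolarDirection
    reaction_time_ms: Optional[float] = None


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found in a trial table."""

    trial_index: int
    field: str
    message: str


@dataclass
class ValidationReport:
    n_trials: int
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _check_trial(t: TrialRecord) -> Iterable[Violation]:
    if t.trial_index < 1:
        yield Violation(t.trial_index, "trial_index",
                        f"trial_index {t.trial_index} < 1")
    if not t.target.within_frontal_hemifield():
        yield Violation(
            t.trial_index, "target",
            f"|α|+|ε| = {t.target.eccentricity_deg:g} > 90",
        )
    # Responses are head-pointing directions and are not constrained to the
    # diamond; only targets (physical speaker positions) are checked.
    if not (LEVEL_DBA_MIN <= t.level_dBA <= LEVEL_DBA_MAX):
        yield Violation(
            t.trial_index, "level_dBA",
            f"level {t.level_dBA:g} dBA outside [{LEVEL_DBA_MIN:g}, {LEVEL_DBA_MAX:g}]",
        )
    if t.reaction_time_ms is not None and t.reaction_time_ms < 0:
        yield Violation(t.trial_index, "reaction_time_ms",
                        f"negative reaction time {t.reaction_time_ms:g} ms")
    if t.phase is Phase.TRAINING:
        if t.target.elevation_deg != 0.0:
            yield Violation(
                t.trial_index, "target",
                f"training target elevation {t.target.elevation_deg:g} != 0",
            )
        if t.target.azimuth_deg not in TRAINING_AZIMUTHS_DEG:
            yield Violation(
                t.trial_index, "target",
                f"training azimuth {t.target.azimuth_deg:g} not in "
                f"{{±12, ±24, ±36, ±48, ±60}}",
            )


def validate_trials(trials: Sequence[TrialRecord]) -> ValidationReport:
    """Check every trial against the domain invariants.

    Returns a report listing each violation with the trial index and the
    offending field.  The input is never mutated.

    Raises
    ------
    ValueError
        If ``trials`` is empty — an empty table is an error, not "all valid".
    """
    trials = list(trials)
    if not trials:
        raise ValueError("cannot validate an empty trial table")
    report = ValidationReport(n_trials=len(trials))
    for t in trials:
        report.violations.extend(_check_trial(t))
    return report
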