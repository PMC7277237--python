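"""Third-molar eruption-potential classification.

Longitudinal work on adolescent cohorts identified a critical third-molar
angulation of 27.0 degrees: teeth angulated beyond it tend to increase
their angulation over time and are unlikely to reach a functional occlusal
position, while teeth below it tend to upright and erupt. Because panoramic
projection distorts angles by a few degrees, calls inside the
[24.5, 29.5] degree interval around the critical angle are additionally
flagged borderline.

Development stage is recorded on a shortened Demirjian scale: follicles
without root formation (stages A-D), starting root bifurcation (stage E),
and root length at least equal to crown height (stages F-H).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import AngleDomainError, StageError

__all__ = [
    "EruptionRule",
    "Verdict",
    "StageClass",
    "EruptionCall",
    "DevelopmentStage",
    "classify_eruption",
    "shorten_demirjian",
    "relative_angle",
]


class Verdict(str, Enum):
    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"


class StageClass(str, Enum):
    NO_ROOTS = "no_roots"
    BIFURCATION = "bifurcation"
    DEVELOPED_ROOTS = "developed_roots"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class EruptionRule:
    """Critical-angle rule with its borderline interval (degrees)."""

    critical_angle_deg: float = 27.0
    borderline_low: float = 24.5
    borderline_high: float = 29.5

    def __post_init__(self):
        if not self.borderline_low <= self.critical_angle_deg <= self.borderline_high:
            raise ValueError(
                "borderline interval must contain the critical angle: "
                f"[{self.borderline_low}, {self.borderline_high}] vs "
                f"{self.critical_angle_deg}"
            )


@dataclass(frozen=True)
class DevelopmentStage:
    """Demirjian stage letter A-H, or unknown (empty)."""

    demirjian: str = ""

    def __post_init__(self):
        letter = self.demirjian.strip().upper()
        if letter and letter not in "ABCDEFGH":
            raise StageError(f"Demirjian stage must be A-H, got {self.demirjian!r}")
        object.__setattr__(self, "demirjian", letter)


@dataclass(frozen=True)
class EruptionCall:
    verdict: Verdict
    borderline: bool
    angle_deg: float
    stage_class: StageClass = StageClass.UNKNOWN


def classify_eruption(
    angle_deg: float, rule: EruptionRule | None = None
) -> EruptionCall:
    """Classify a third molar's eruption potential from its angle magnitude.

    Unfavorable iff the angle is *strictly greater* than the critical
    angle (27.0 degrees by default); exactly 27.0 is favorable. The
    borderline flag is set for angles inside [borderline_low,
    borderline_high], bounds inclusive, regardless of the verdict.
    """
    rule = rule or EruptionRule()
    if not 0 <= angle_deg <= 90:
        raise AngleDomainError(
            f"angle magnitude must be in [0, 90] degrees, got {angle_deg}"
        )
    verdict = (
        Verdict.UNFAVORABLE
        if angle_deg > rule.critical_angle_deg
        else Verdict.FAVORABLE
    )
    borderline = rule.borderline_low <= angle_deg <= rule.borderline_high
    return EruptionCall(
        verdict=verdict, borderline=borderline, angle_deg=float(angle_deg)
    )


def shorten_demirjian(stage: DevelopmentStage | str) -> StageClass:
    """Map a Demirjian letter to the shortened three-class scale.

    A-D -> no_roots, E -> bifurcation, F-H -> developed_roots; an unknown
    stage passes through.
    """
    if isinstance(stage, str):
        stage = DevelopmentStage(stage)
    letter = stage.demirjian
    if not letter:
        return StageClass.UNKNOWN
    if letter in "ABCD":
        return StageClass.NO_ROOTS
    if letter == "E":
        return StageClass.BIFURCATION
    return StageClass.DEVELOPED_ROOTS


def relative_angle(m3_angle_deg: float, m2_angle_deg: float) -> float:
    """Third-molar angle relative to the ipsilateral second molar's axis.

    The critical-angle rule was derived with the second molar's vertical
    axis as reference; when both teeth are measured in the image frame the
    relative angulation is the magnitude of the signed difference.
    """
    return abs(m3_angle_deg - m2_angle_deg)
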