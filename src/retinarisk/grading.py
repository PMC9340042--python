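"""Retinopathy grading scale, the referable-DR outcome, and two-screening risk groups.

The English screening-programme R/M scale grades each eye separately:
``R0`` no retinopathy, ``R1`` mild (background) non-proliferative DR,
``R2`` pre-proliferative DR, ``R3`` proliferative DR, with a separate
maculopathy flag ``M0``/``M1``.  Referable diabetic retinopathy (RDR) —
the screening programme's referral trigger — is maculopathy or R2/R3 in
either eye.

Risk groups A–I classify a patient by the combination of per-eye R0/R1
status at the first two screening episodes.  Groups B and C (retinopathy
present at the first screening but absent at the second, i.e. apparent
regression) are excluded by design: the screening-grades-only risk model
was never fitted for them.  Any grade combination involving R2/R3,
maculopathy, or an ungradable eye at either defining screening makes the
patient ineligible for risk-group classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Optional

__all__ = [
    "EyeGrade",
    "ScreeningEpisode",
    "BaselineCategory",
    "RiskGroup",
    "ELIGIBLE_GROUPS",
    "EXCLUDED_GROUPS",
    "UngradableEpisodeError",
    "is_rdr",
    "baseline_category",
    "classify_risk_group",
]


class UngradableEpisodeError(ValueError):
    """Raised when an operation requires at least one gradable eye and none exists."""


@dataclass(frozen=True)
class EyeGrade:
    """Grade of a single gradable eye.

    An ungradable eye is represented as ``None`` at the episode level,
    never as an ``EyeGrade`` — in particular never silently as R0M0.
    """

    retinopathy: int  # 0..3 for R0..R3
    maculopathy: int  # 0 or 1 for M0/M1

    def __post_init__(self) -> None:
        if self.retinopathy not in (0, 1, 2, 3):
            raise ValueError(f"retinopathy grade must be 0..3, got {self.retinopathy!r}")
        if self.maculopathy not in (0, 1):
            raise ValueError(f"maculopathy flag must be 0 or 1, got {self.maculopathy!r}")

    def __str__(self) -> str:  # e.g. "R1M0"
        return f"R{self.retinopathy}M{self.maculopathy}"


@dataclass(frozen=True)
class ScreeningEpisode:
    """One dated retinal screening with per-eye grades; ``None`` marks an ungradable eye."""

    patient_id: str
    date: date
    right_eye: Optional[EyeGrade] = None
    left_eye: Optional[EyeGrade] = None

    @property
    def gradable_eyes(self) -> tuple[EyeGrade, ...]:
        return tuple(e for e in (self.right_eye, self.left_eye) if e is not None)

    @property
    def is_gradable(self) -> bool:
        return len(self.gradable_eyes) > 0


class BaselineCategory(str, Enum):
    """Per-episode DR category used to define risk groups.

    Only R0/R1 with no maculopathy in both eyes qualifies for the three
    named categories; anything else — R2/R3, M1, or an ungradable eye —
    is OTHER and makes the patient ineligible for risk grouping.
    """

    NO_DR = "NO_DR"
    MILD_ONE_EYE = "MILD_ONE_EYE"
    MILD_BOTH_EYES = "MILD_BOTH_EYES"
    OTHER = "OTHER"


class RiskGroup(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"
    I = "I"
    INELIGIBLE = "INELIGIBLE"

    @property
    def excluded(self) -> bool:
        """True for the regression groups B and C, excluded from all scoring."""
        return self in EXCLUDED_GROUPS


EXCLUDED_GROUPS = frozenset({RiskGroup.B, RiskGroup.C})
ELIGIBLE_GROUPS = frozenset(
    {RiskGroup.A, RiskGroup.D, RiskGroup.E, RiskGroup.F, RiskGroup.G, RiskGroup.H, RiskGroup.I}
)


def is_rdr(episode: ScreeningEpisode) -> bool:
    """Whether the episode shows referable DR in any gradable eye.

    RDR is R1M1 (maculopathy), R2M0/R2M1 (pre-proliferative DR) or
    R3M0/R3M1 (proliferative DR) in either eye.  Maculopathy is referable
    regardless of the R level, so the unusual R0M1 combination also counts.
    Classification uses gradable eyes only; a fully ungradable episode
    raises :class:`UngradableEpisodeError`.
    """
    eyes = episode.gradable_eyes
    if not eyes:
        raise UngradableEpisodeError(
            f"episode for patient {episode.patient_id} on {episode.date} has no gradable eye"
        )
    return any(e.maculopathy == 1 or e.retinopathy >= 2 for e in eyes)


def baseline_category(episode: ScreeningEpisode) -> BaselineCategory:
    """Classify an episode into NO_DR / MILD_ONE_EYE / MILD_BOTH_EYES / OTHER.

    Both eyes must be gradable for the three named categories (risk-group
    classification requires both-eye status); one ungradable eye with the
    other gradable yields OTHER.  Raises :class:`UngradableEpisodeError`
    when neither eye is gradable.
    """
    if not episode.is_gradable:
        raise UngradableEpisodeError(
            f"episode for patient {episode.patient_id} on {episode.date} has no gradable eye"
        )
    right, left = episode.right_eye, episode.left_eye
    if right is None or left is None:
        return BaselineCategory.OTHER
    if any(e.maculopathy == 1 or e.retinopathy >= 2 for e in (right, left)):
        return BaselineCategory.OTHER
    n_mild = sum(1 for e in (right, left) if e.retinopathy == 1)
    if n_mild == 0:
        return BaselineCategory.NO_DR
    if n_mild == 1:
        return BaselineCategory.MILD_ONE_EYE
    return BaselineCategory.MILD_BOTH_EYES


# (category at first screening, category at second screening) -> group
_GROUP_GRID: dict[tuple[BaselineCategory, BaselineCategory], RiskGroup] = {
    (BaselineCategory.NO_DR, BaselineCategory.NO_DR): RiskGroup.A,
    (BaselineCategory.MILD_ONE_EYE, BaselineCategory.NO_DR): RiskGroup.B,
    (BaselineCategory.MILD_BOTH_EYES, BaselineCategory.NO_DR): RiskGroup.C,
    (BaselineCategory.NO_DR, BaselineCategory.MILD_ONE_EYE): RiskGroup.D,
    (BaselineCategory.MILD_ONE_EYE, BaselineCategory.MILD_ONE_EYE): RiskGroup.E,
    (BaselineCategory.MILD_BOTH_EYES, BaselineCategory.MILD_ONE_EYE): RiskGroup.F,
    (BaselineCategory.NO_DR, BaselineCategory.MILD_BOTH_EYES): RiskGroup.G,
    (BaselineCategory.MILD_ONE_EYE, BaselineCategory.MILD_BOTH_EYES): RiskGroup.H,
    (BaselineCategory.MILD_BOTH_EYES, BaselineCategory.MILD_BOTH_EYES): RiskGroup.I,
}


def classify_risk_group(first: ScreeningEpisode, second: ScreeningEpisode) -> RiskGroup:
    """Risk group from the categories at the first two screening episodes.

    The 3x3 grid of (first, second) categories over {no DR, mild in one
    eye, mild in both eyes} maps to groups A–I; OTHER at either episode
    (including R2/R3, maculopathy or an ungradable eye) is INELIGIBLE.
    Requires both episodes from the same patient with ``first.date``
    strictly before ``second.date``.
    """
    if first.patient_id != second.patient_id:
        raise ValueError(
            f"episodes belong to different patients: {first.patient_id!r} vs {second.patient_id!r}"
        )
    if not first.date < second.date:
        raise ValueError(
            f"first episode ({first.date}) must precede second episode ({second.date})"
        )
    cat1 = baseline_category(first)
    cat2 = baseline_category(second)
    if BaselineCategory.OTHER in (cat1, cat2):
        return RiskGroup.INELIGIBLE
    return _GROUP_GRID[(cat1, cat2)]
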