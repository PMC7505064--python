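"""Photograph scoring, the reject rule and posture categories.

Each lateral photograph is graded 1 (good) / 2 (medium) / 3 (poor) on nine
attributes: five photography attributes (camera focus, vertical camera
tilt, horizontal camera angle, height measurability, length measurability)
and four posture attributes (body arch, body straightness, neck flexing,
neck lateral bending). Any score of 3 removes the photograph from analysis.

Passing photographs fall into posture categories: "Good" (every attribute
scored 1), "BS" / "NF" / "NB" (a score of 2 on exactly one of body
straightness, neck flexing or neck lateral bending, all else 1), or
unusable (any other pattern of 2s, which the analysis excludes).

Each ratio method tolerates a different set of postures: methods that span
the nose (TH:HBL, TH:EBL) are only reliable on "Good" photographs, TH:PBL
additionally tolerates neck flexing, and the torso-only TH:HTL tolerates
everything except a bent body axis — which is why TH:HTL is the adopted
field indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

__all__ = [
    "PHOTOGRAPHY_ATTRIBUTES",
    "POSTURE_ATTRIBUTES",
    "ALL_ATTRIBUTES",
    "PhotoScores",
    "PostureCategory",
    "RatioMethod",
    "passes_quality_filter",
    "assign_posture_category",
    "eligible_categories_for_method",
]

PHOTOGRAPHY_ATTRIBUTES = (
    "focus",
    "camera_tilt",
    "camera_angle",
    "height_measurability",
    "length_measurability",
)
POSTURE_ATTRIBUTES = (
    "body_arch",
    "body_straightness",
    "neck_flexing",
    "neck_bending",
)
ALL_ATTRIBUTES = PHOTOGRAPHY_ATTRIBUTES + POSTURE_ATTRIBUTES


@dataclass(frozen=True)
class PhotoScores:
    """Nine attribute scores, each 1, 2 or 3."""

    focus: int = 1
    camera_tilt: int = 1
    camera_angle: int = 1
    height_measurability: int = 1
    length_measurability: int = 1
    body_arch: int = 1
    body_straightness: int = 1
    neck_flexing: int = 1
    neck_bending: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (1, 2, 3):
                raise ValueError(f"{f.name} score must be 1, 2 or 3 (got {v})")

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def total(self) -> int:
        """Sum of all nine scores; lower is better ("best photo" ordering)."""
        return sum(self.as_dict().values())


class PostureCategory(str, Enum):
    GOOD = "Good"
    BS = "BS"  # body straightness scored 2
    NF = "NF"  # neck flexing scored 2
    NB = "NB"  # neck lateral bending scored 2
    UNUSABLE = "unusable"


class RatioMethod(str, Enum):
    """The four torso-height : length ratio definitions."""

    TH_HBL = "TH:HBL"
    TH_EBL = "TH:EBL"
    TH_PBL = "TH:PBL"
    TH_HTL = "TH:HTL"


def passes_quality_filter(scores: PhotoScores) -> bool:
    """True iff no attribute scored 3."""
    return all(v != 3 for v in scores.as_dict().values())


def assign_posture_category(
    scores: PhotoScores, strict_photography: bool = True
) -> PostureCategory:
    """Deterministic posture category for a quality-passing photograph.

    With ``strict_photography`` (default) the category definitions read
    "score of 1 for all [other] attributes" literally: a photography
    attribute scored 2 makes the photo unusable. With the relaxed switch,
    photography attributes are ignored and only the four posture attributes
    decide the category.
    """
    if not passes_quality_filter(scores):
        raise ValueError("posture category is undefined for rejected photographs")

    d = scores.as_dict()
    if strict_photography and any(d[a] == 2 for a in PHOTOGRAPHY_ATTRIBUTES):
        return PostureCategory.UNUSABLE

    posture_twos = [a for a in POSTURE_ATTRIBUTES if d[a] == 2]
    if not posture_twos:
        return PostureCategory.GOOD
    if posture_twos == ["body_straightness"]:
        return PostureCategory.BS
    if posture_twos == ["neck_flexing"]:
        return PostureCategory.NF
    if posture_twos == ["neck_bending"]:
        return PostureCategory.NB
    # body_arch == 2, or multiple posture attributes scored 2
    return PostureCategory.UNUSABLE


_ELIGIBLE: dict[RatioMethod, frozenset[PostureCategory]] = {
    RatioMethod.TH_HBL: frozenset({PostureCategory.GOOD}),
    RatioMethod.TH_EBL: frozenset({PostureCategory.GOOD}),
    RatioMethod.TH_PBL: frozenset({PostureCategory.GOOD, PostureCategory.NF}),
    RatioMethod.TH_HTL: frozenset(
        {PostureCategory.GOOD, PostureCategory.NF, PostureCategory.NB}
    ),
}


def eligible_categories_for_method(
    method: RatioMethod | str,
) -> frozenset[PostureCategory]:
    """Posture categories whose ratio means are indistinguishable from Good.

    These are the categories a method may pool over in field use; Good is
    eligible for every method.
    """
    return _ELIGIBLE[RatioMethod(method)]
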