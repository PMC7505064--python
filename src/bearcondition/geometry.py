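"""Landmark geometry: pixel-space morphometrics from photo annotations.

Landmarks are named pixel coordinates in image convention (origin top-left,
y increasing downward). Before measuring, coordinates are rotated so the
ground line is horizontal ("ground alignment"); "horizontal" distances are
then x-differences (projections onto the ground) and torso height is the
y-difference perpendicular to the ground.

Measures (all in pixels):

* TH  — torso height: vertical distance from the lowest point of the
  abdomen to the highest point of the waist.
* HBL — horizontal body length: |x| distance nose tip to tail base.
* EBL — Euclidean body length: straight-line nose tip to tail base.
* HTL — horizontal torso length: |x| distance tail base to shoulder top.
* PBL — polygonal body length: HTL plus the Euclidean segments shoulder
  top -> ear base -> nose tip.

Condition ratios are TH divided by one of the four lengths; with replicate
tracings the ratio of the replicate means is used (mean TH over mean
length), not the mean of per-replicate ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "MeasurementSet",
    "align_to_ground",
    "measure",
    "condition_ratio",
    "ratio_from_replicates",
]

LANDMARK_NAMES = (
    "nose_tip",
    "tail_base",
    "shoulder_top",
    "ear_base",
    "abdomen_lowest",
    "waist_top",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Named pixel landmarks plus the ground-line angle.

    ``ground_angle`` is the counterclockwise tilt (degrees) of the ground
    line relative to the image horizontal; |angle| must be < 45. Landmarks
    may be a subset of :data:`LANDMARK_NAMES`; measures needing a missing
    landmark are simply not computed.
    """

    landmarks: Mapping[str, tuple[float, float]]
    ground_angle: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.ground_angle) < 45.0:
            raise ValueError("|ground_angle| must be < 45 degrees")
        clean = {}
        for name, xy in dict(self.landmarks).items():
            if name not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark {name!r}")
            x, y = float(xy[0]), float(xy[1])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinates for {name}")
            clean[name] = (x, y)
        object.__setattr__(self, "landmarks", clean)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.landmarks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks


def _rotate(xy: tuple[float, float], degrees: float) -> tuple[float, float]:
    # Counterclockwise on-screen rotation in the y-down image convention.
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    x, y = xy
    # y-down: flip to y-up, rotate CCW, flip back
    return (c * x + s * y, -s * x + c * y)


def align_to_ground(landmarks: LandmarkSet) -> LandmarkSet:
    """Rotate all coordinates about the origin so the ground is horizontal.

    An isometry: pairwise distances are preserved; the returned set has
    ``ground_angle = 0``.
    """
    a = landmarks.ground_angle
    if a == 0.0:
        return landmarks
    rotated = {n: _rotate(xy, -a) for n, xy in landmarks.landmarks.items()}
    return LandmarkSet(landmarks=rotated, ground_angle=0.0)


@dataclass(frozen=True)
class MeasurementSet:
    """Pixel measurements from one photograph; absent fields are None."""

    th: Optional[float] = None
    hbl: Optional[float] = None
    ebl: Optional[float] = None
    pbl: Optional[float] = None
    htl: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("th", "hbl", "ebl", "pbl", "htl"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present")
        if self.ebl is not None and self.hbl is not None and self.ebl < self.hbl:
            raise ValueError("EBL must be >= HBL (Euclidean vs projection)")
        if self.pbl is not None and self.htl is not None and self.pbl < self.htl:
            raise ValueError("PBL must be >= HTL (polygon includes HTL segment)")


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def measure(landmarks: LandmarkSet) -> MeasurementSet:
    """Compute TH/HBL/EBL/PBL/HTL from a ground-aligned landmark set.

    Raises if the set is not aligned (``ground_angle`` must be 0). Missing
    landmarks silently drop the measures that need them.
    """
    if landmarks.ground_angle != 0.0:
        raise ValueError("landmarks must be ground-aligned before measuring")
    lm = landmarks.landmarks

    th = hbl = ebl = pbl = htl = None
    if "abdomen_lowest" in lm and "waist_top" in lm:
        th = abs(lm["abdomen_lowest"][1] - lm["waist_top"][1])
    if "nose_tip" in lm and "tail_base" in lm:
        hbl = abs(lm["nose_tip"][0] - lm["tail_base"][0])
        ebl = _dist(lm["nose_tip"], lm["tail_base"])
    if "tail_base" in lm and "shoulder_top" in lm:
        htl = abs(lm["tail_base"][0] - lm["shoulder_top"][0])
        if "ear_base" in lm and "nose_tip" in lm:
            pbl = (
                htl
                + _dist(lm["shoulder_top"], lm["ear_base"])
                + _dist(lm["ear_base"], lm["nose_tip"])
            )
    return MeasurementSet(th=th, hbl=hbl, ebl=ebl, pbl=pbl, htl=htl)


def condition_ratio(th: float, length: float) -> float:
    """Torso height divided by a length measure from the same photo."""
    if not th > 0 or not length > 0:
        raise ValueError("th and length must be strictly positive")
    return th / length


def ratio_from_replicates(th_series: Sequence[float],
                          length_series: Sequence[float]) -> float:
    """Ratio of replicate means: mean(TH) / mean(length).

    Replicate tracings of the same photograph are averaged per measure
    before the ratio is formed, which suppresses tracing noise more
    effectively than averaging per-replicate ratios.
    """
    th = np.asarray(th_series, dtype=float)
    ln = np.asarray(length_series, dtype=float)
    if th.size == 0 or ln.size == 0:
        raise ValueError("replicate series must be non-empty")
    return condition_ratio(float(th.mean()), float(ln.mean()))
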