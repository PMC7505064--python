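"""Synthetic field data with the statistical structure the analysis assumes.

Every stage of the package is testable offline against generators whose
defaults are the published study conditions for the Shiretoko population:

* capture records — ages drawn per age-sex class (class composition from
  the published season x class table), lengths from the sex-specific von
  Bertalanffy curves plus Gaussian noise, and log-normal allometric mass
  scatter around ln W = b ln L + a with additive season and class effects
  expressed in BCI (residual-SD) units;
* replicate photo measurements — per-photo torso-height/length ratios at
  the published posture-category means, with multiplicative tracing noise
  at the published within-photo CVs;
* landmark sets — coordinates constructed to realize a target measurement
  set exactly, then rotated to a ground angle and jittered;
* seasonal photo series and capture-photo calibration studies for the
  end-to-end pipeline.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import SHIRETOKO_REFERENCE_MODEL, AllometricModel
from .geometry import LandmarkSet, MeasurementSet, measure
from .growth import (
    FEMALE_SHIRETOKO_PARAMS,
    MALE_SHIRETOKO_PARAMS,
    VonBertalanffyParams,
    _vb,
)
from .photo_quality import PhotoScores, PostureCategory, RatioMethod
from .pipeline import PhotoObservation
from .records import AgeClass, BearRecord, Season, Sex, Source

__all__ = [
    "PopulationSpec",
    "PhotoSimSpec",
    "generate_population",
    "generate_replicate_measurements",
    "generate_landmarks",
    "generate_seasonal_photos",
    "generate_calibration_study",
    "DEFAULT_SEASONAL_TRAJECTORY",
    "TABLE_CATEGORY_STATS",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Capture-record population
# ---------------------------------------------------------------------------

#: Published season x age-sex class composition of the 476 analysed bears.
#: Note the empty female-cub x spring cell: no female cubs were sampled in
#: spring, which reduces the estimable interaction df in the two-way ANOVA
#: from 10 to 9.
DEFAULT_CELL_COUNTS: dict[tuple[Sex, AgeClass, Season], int] = {
    (Sex.FEMALE, AgeClass.ADULT, Season.SPRING): 14,
    (Sex.FEMALE, AgeClass.ADULT, Season.SUMMER): 35,
    (Sex.FEMALE, AgeClass.ADULT, Season.AUTUMN): 43,
    (Sex.FEMALE, AgeClass.SUBADULT, Season.SPRING): 27,
    (Sex.FEMALE, AgeClass.SUBADULT, Season.SUMMER): 46,
    (Sex.FEMALE, AgeClass.SUBADULT, Season.AUTUMN): 32,
    (Sex.FEMALE, AgeClass.CUB, Season.SPRING): 0,
    (Sex.FEMALE, AgeClass.CUB, Season.SUMMER): 3,
    (Sex.FEMALE, AgeClass.CUB, Season.AUTUMN): 5,
    (Sex.MALE, AgeClass.ADULT, Season.SPRING): 4,
    (Sex.MALE, AgeClass.ADULT, Season.SUMMER): 24,
    (Sex.MALE, AgeClass.ADULT, Season.AUTUMN): 13,
    (Sex.MALE, AgeClass.SUBADULT, Season.SPRING): 77,
    (Sex.MALE, AgeClass.SUBADULT, Season.SUMMER): 91,
    (Sex.MALE, AgeClass.SUBADULT, Season.AUTUMN): 43,
    (Sex.MALE, AgeClass.CUB, Season.SPRING): 1,
    (Sex.MALE, AgeClass.CUB, Season.SUMMER): 6,
    (Sex.MALE, AgeClass.CUB, Season.AUTUMN): 12,
}

#: Pooled seasonal BCI means (spring, summer, autumn).
DEFAULT_SEASON_OFFSETS: dict[Season, float] = {
    Season.SPRING: -0.20,
    Season.SUMMER: -0.03,
    Season.AUTUMN: 0.36,
}

#: Class BCI offsets: published class x season means pooled over seasons.
DEFAULT_CLASS_OFFSETS: dict[tuple[Sex, AgeClass], float] = {
    (Sex.FEMALE, AgeClass.ADULT): -0.03,
    (Sex.FEMALE, AgeClass.SUBADULT): -0.14,
    (Sex.FEMALE, AgeClass.CUB): 0.09,
    (Sex.MALE, AgeClass.ADULT): 0.65,
    (Sex.MALE, AgeClass.SUBADULT): 0.05,
    (Sex.MALE, AgeClass.CUB): 0.12,
}

_SEASON_MONTHS = {
    Season.SPRING: (4, 5, 6),
    Season.SUMMER: (7, 8),
    Season.AUTUMN: (9, 10, 11),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Generating truth for a synthetic capture-record population."""

    cell_counts: Mapping[tuple[Sex, AgeClass, Season], int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_COUNTS)
    )
    allometry: AllometricModel = SHIRETOKO_REFERENCE_MODEL
    season_offsets: Mapping[Season, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_OFFSETS)
    )
    class_offsets: Mapping[tuple[Sex, AgeClass], float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_OFFSETS)
    )
    vb_female: VonBertalanffyParams = FEMALE_SHIRETOKO_PARAMS
    vb_male: VonBertalanffyParams = MALE_SHIRETOKO_PARAMS
    length_noise_sd: float = 8.0  # cm around the growth curve
    noise_scale: float = 1.0  # multiplies the allometric residual noise
    adult_max_age: int = 20
    n_torso_height: int = 23  # adult females carrying a torso-height value
    th_bl_mean: float = 0.45
    th_bl_sd: float = 0.018
    th_bl_coupling: float = 0.81  # correlation of TH:BL with BCI
    n_duplicates: int = 0  # extra younger-age recaptures of existing bears
    year_range: tuple[int, int] = (1998, 2017)

    @property
    def n(self) -> int:
        return sum(self.cell_counts.values())


def _draw_age(sex: Sex, age_class: AgeClass, max_age: int,
              rng: np.random.Generator) -> int:
    if age_class is AgeClass.CUB:
        return 0
    hi = 4 if sex is Sex.FEMALE else 7
    if age_class is AgeClass.SUBADULT:
        return int(rng.integers(1, hi + 1))
    lo = hi + 1
    return int(rng.integers(lo, max_age + 1))


def _draw_date(season: Season, year_range: tuple[int, int],
               rng: np.random.Generator) -> dt.date:
    year = int(rng.integers(year_range[0], year_range[1] + 1))
    month = int(rng.choice(_SEASON_MONTHS[season]))
    day = int(rng.integers(1, 29))
    return dt.date(year, month, day)


def generate_population(spec: PopulationSpec = PopulationSpec(),
                        seed=None) -> list[BearRecord]:
    """Draw a synthetic capture-record population.

    For each bear: an age within its class, a body length from the
    sex-specific growth curve plus Gaussian noise, a sampling date drawn by
    season, and a log-normal mass around the allometric line with the
    season and class effects (in residual-SD units) added to the ln-scale
    residual. When ``n_duplicates`` > 0, that many bears also receive an
    extra record at a strictly younger age and earlier date (repeated
    captures for dedupe testing); torso height is attached to
    ``n_torso_height`` randomly chosen adult females with a TH:BL ratio
    correlated with the bear's realized BCI at ``th_bl_coupling``.
    """
    rng = _rng(seed)
    m = spec.allometry

    records: list[BearRecord] = []
    adult_female_idx: list[int] = []
    idx = 0
    for (sex, age_class, season), count in spec.cell_counts.items():
        vb = spec.vb_female if sex is Sex.FEMALE else spec.vb_male
        for _ in range(count):
            age = _draw_age(sex, age_class, spec.adult_max_age, rng)
            length = _vb(age, vb.a_inf, vb.k, vb.t0) + rng.normal(
                0.0, spec.length_noise_sd
            )
            length = float(max(length, 30.0))
            date = _draw_date(season, spec.year_range, rng)
            offset = (
                spec.season_offsets[season]
                + spec.class_offsets[(sex, age_class)]
            )
            resid = m.resid_sd * (
                offset + spec.noise_scale * rng.normal()
            )
            ln_mass = m.slope * math.log(length) + m.intercept + resid
            records.append(
                BearRecord(
                    bear_id=f"B{idx:04d}",
                    sex=sex,
                    date=date,
                    body_mass=math.exp(ln_mass),
                    body_length=length,
                    age_years=age,
                    source=Source.CONTROL_KILL,
                )
            )
            if sex is Sex.FEMALE and age_class is AgeClass.ADULT:
                adult_female_idx.append(idx)
            idx += 1

    # Torso height on a subset of adult females, coupled to realized BCI.
    if spec.n_torso_height > 0 and adult_female_idx:
        chosen = rng.choice(
            adult_female_idx,
            size=min(spec.n_torso_height, len(adult_female_idx)),
            replace=False,
        )
        c = spec.th_bl_coupling
        for i in chosen:
            r = records[i]
            bci = (
                math.log(r.body_mass) - m.slope * math.log(r.body_length)
                - m.intercept
            ) / m.resid_sd
            th_bl = spec.th_bl_mean + spec.th_bl_sd * (
                c * bci + math.sqrt(max(0.0, 1 - c * c)) * rng.normal()
            )
            th_bl = min(max(th_bl, 0.05), 0.95)
            records[i] = replace(r, torso_height=th_bl * r.body_length)

    # Repeated captures: duplicate ids at strictly younger ages.
    if spec.n_duplicates > 0:
        eligible = [r for r in records if (r.age_years or 0) >= 1]
        picks = rng.choice(len(eligible), size=min(spec.n_duplicates,
                                                   len(eligible)),
                           replace=False)
        for j in picks:
            r = eligible[int(j)]
            young_age = int(rng.integers(0, r.age_years))
            vb = spec.vb_female if r.sex is Sex.FEMALE else spec.vb_male
            length = float(max(
                _vb(young_age, vb.a_inf, vb.k, vb.t0)
                + rng.normal(0.0, spec.length_noise_sd),
                30.0,
            ))
            ln_mass = (
                m.slope * math.log(length) + m.intercept
                + m.resid_sd * spec.noise_scale * rng.normal()
            )
            back = int(r.age_years - young_age)
            records.append(
                BearRecord(
                    bear_id=r.bear_id,
                    sex=r.sex,
                    date=dt.date(max(r.date.year - back, 1990), r.date.month,
                                 r.date.day),
                    body_mass=math.exp(ln_mass),
                    body_length=length,
                    age_years=young_age,
                    source=Source.RESEARCH_CAPTURE,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Replicate photo measurements
# ---------------------------------------------------------------------------

#: Published posture-category ratio means and SDs per measurement method.
TABLE_CATEGORY_STATS: dict[RatioMethod, dict[PostureCategory, tuple[float, float]]] = {
    RatioMethod.TH_HBL: {
        PostureCategory.GOOD: (0.416, 0.010),
        PostureCategory.BS: (0.454, 0.020),
        PostureCategory.NF: (0.444, 0.015),
        PostureCategory.NB: (0.435, 0.014),
    },
    RatioMethod.TH_EBL: {
        PostureCategory.GOOD: (0.409, 0.009),
        PostureCategory.BS: (0.431, 0.017),
        PostureCategory.NF: (0.428, 0.014),
        PostureCategory.NB: (0.428, 0.014),
    },
    RatioMethod.TH_PBL: {
        PostureCategory.GOOD: (0.394, 0.011),
        PostureCategory.BS: (0.413, 0.015),
        PostureCategory.NF: (0.401, 0.013),
        PostureCategory.NB: (0.412, 0.014),
    },
    RatioMethod.TH_HTL: {
        PostureCategory.GOOD: (0.711, 0.025),
        PostureCategory.BS: (0.762, 0.034),
        PostureCategory.NF: (0.721, 0.028),
        PostureCategory.NB: (0.736, 0.028),
    },
}

#: Published within-photo tracing CVs (percent) per pixel measure.
DEFAULT_REPLICATE_CV: dict[str, float] = {
    "th": 0.29,
    "hbl": 0.27,
    "ebl": 0.29,
    "pbl": 0.26,
    "htl": 0.45,
}

_METHOD_LENGTH = {
    RatioMethod.TH_HBL: "hbl",
    RatioMethod.TH_EBL: "ebl",
    RatioMethod.TH_PBL: "pbl",
    RatioMethod.TH_HTL: "htl",
}


@dataclass(frozen=True)
class PhotoSimSpec:
    """Generating truth for replicate photo-measurement series."""

    category_stats: Mapping[RatioMethod, Mapping[PostureCategory, tuple[float, float]]] = field(
        default_factory=lambda: {
            m: dict(v) for m, v in TABLE_CATEGORY_STATS.items()
        }
    )
    replicate_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATE_CV)
    )  # percent
    photos_per_category: Mapping[PostureCategory, int] = field(
        default_factory=lambda: {
            PostureCategory.GOOD: 15,
            PostureCategory.BS: 9,
            PostureCategory.NF: 10,
            PostureCategory.NB: 9,
        }
    )
    th_base_px: float = 100.0
    th_photo_cv: float = 3.0  # percent, photo-to-photo scale variation


def generate_replicate_measurements(
    spec: PhotoSimSpec = PhotoSimSpec(),
    n_replicates: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Simulate replicate pixel tracings of posture-classified photographs.

    Per photo, one standard-normal posture/condition draw scales every
    method's ratio by that method's category CV (a shared draw keeps the
    method ratios ordered as geometry requires); the photo's true torso
    height sets the per-method true lengths, and each replicate tracing
    multiplies every measure by independent Gaussian noise at its published
    within-photo CV. Returns a long DataFrame with one row per (photo,
    replicate) and columns th, hbl, ebl, pbl, htl (pixels).
    """
    rng = _rng(seed)
    rows = []
    pid = 0
    for category, n_photos in spec.photos_per_category.items():
        for _ in range(n_photos):
            z = rng.normal()
            th_true = spec.th_base_px * (
                1.0 + (spec.th_photo_cv / 100.0) * rng.normal()
            )
            lengths_true = {}
            for method, length_key in _METHOD_LENGTH.items():
                mean, sd = spec.category_stats[method][category]
                ratio = mean * (1.0 + (sd / mean) * z)
                lengths_true[length_key] = th_true / ratio
            for rep in range(n_replicates):
                row = {
                    "photo_id": f"P{pid:04d}",
                    "category": category.value,
                    "replicate": rep + 1,
                    "th": th_true
                    * (1.0 + spec.replicate_cv["th"] / 100.0 * rng.normal()),
                }
                for key, true_len in lengths_true.items():
                    row[key] = true_len * (
                        1.0 + spec.replicate_cv[key] / 100.0 * rng.normal()
                    )
                rows.append(row)
            pid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Landmark construction
# ---------------------------------------------------------------------------

def generate_landmarks(
    targets: MeasurementSet,
    ground_angle: float = 0.0,
    jitter: float = 0.0,
    seed=None,
) -> LandmarkSet:
    """Construct a landmark set realizing target measures exactly at jitter 0.

    Coordinates are built in the ground-aligned frame (tail base at
    (200, 100), animal facing left), rotated by ``ground_angle`` so that
    :func:`~bearcondition.geometry.align_to_ground` recovers the aligned
    frame, and optionally perturbed with i.i.d. Gaussian coordinate jitter
    (pixel SD). Requires a full target set with EBL >= HBL and
    PBL - HTL >= the shoulder-to-nose distance (ellipse feasibility for the
    ear placement); infeasible targets raise ValueError.
    """
    t = targets
    if None in (t.th, t.hbl, t.ebl, t.pbl, t.htl):
        raise ValueError("all five target measures are required")

    tail = (200.0, 100.0)
    shoulder = (tail[0] - t.htl, 85.0)
    dy = math.sqrt(max(t.ebl**2 - t.hbl**2, 0.0))
    nose = (tail[0] - t.hbl, tail[1] - dy)

    # Ear lies on the ellipse with foci (shoulder, nose) and segment-sum
    # PBL - HTL; place it on the minor axis above the chord.
    s = t.pbl - t.htl
    chord = math.dist(shoulder, nose)
    if s < chord:
        raise ValueError(
            "infeasible targets: PBL - HTL shorter than shoulder-nose distance"
        )
    a_semi = s / 2.0
    c_semi = chord / 2.0
    b_semi = math.sqrt(max(a_semi**2 - c_semi**2, 0.0))
    mid = ((shoulder[0] + nose[0]) / 2.0, (shoulder[1] + nose[1]) / 2.0)
    if chord > 0:
        ux, uy = ((nose[0] - shoulder[0]) / chord, (nose[1] - shoulder[1]) / chord)
    else:
        ux, uy = 1.0, 0.0
    # normal pointing upward on screen (negative y)
    nx, ny = uy, -ux
    if ny > 0:
        nx, ny = -nx, -ny
    ear = (mid[0] + b_semi * nx, mid[1] + b_semi * ny)

    x_torso = tail[0] - t.htl / 2.0
    waist = (x_torso, 30.0)
    abdomen = (x_torso, 30.0 + t.th)

    lm = {
        "nose_tip": nose,
        "tail_base": tail,
        "shoulder_top": shoulder,
        "ear_base": ear,
        "abdomen_lowest": abdomen,
        "waist_top": waist,
    }
    from .geometry import _rotate

    if ground_angle != 0.0:
        lm = {k: _rotate(v, ground_angle) for k, v in lm.items()}
    if jitter > 0.0:
        rng = _rng(seed)
        lm = {
            k: (v[0] + rng.normal(0.0, jitter), v[1] + rng.normal(0.0, jitter))
            for k, v in lm.items()
        }
    return LandmarkSet(landmarks=lm, ground_angle=ground_angle)


# ---------------------------------------------------------------------------
# Seasonal photo series and calibration studies
# ---------------------------------------------------------------------------

#: Half-month TH:HTL trajectory (month, half) -> true ratio, late June to
#: early October, with the published late-August minimum and early-October
#: maximum.
DEFAULT_SEASONAL_TRAJECTORY: dict[tuple[int, str], float] = {
    (6, "late"): 0.660,
    (7, "early"): 0.670,
    (7, "late"): 0.660,
    (8, "early"): 0.600,
    (8, "late"): 0.567,
    (9, "early"): 0.680,
    (9, "late"): 0.700,
    (10, "early"): 0.714,
}


def _photo_from_ratio(photo_id: str, bear_id: str, date: dt.date, ratio: float,
                      rng: np.random.Generator, n_replicates: int = 3,
                      th_px: float = 100.0,
                      scores: PhotoScores | None = None) -> PhotoObservation:
    cv_th = DEFAULT_REPLICATE_CV["th"] / 100.0
    cv_htl = DEFAULT_REPLICATE_CV["htl"] / 100.0
    htl_px = th_px / ratio
    th = tuple(th_px * (1.0 + cv_th * rng.normal()) for _ in range(n_replicates))
    htl = tuple(htl_px * (1.0 + cv_htl * rng.normal())
                for _ in range(n_replicates))
    return PhotoObservation(
        photo_id=photo_id,
        bear_id=bear_id,
        date=date,
        scores=scores or PhotoScores(),
        th_px=th,
        htl_px=htl,
    )


def generate_seasonal_photos(
    trajectory: Mapping[tuple[int, str], float] | None = None,
    years: Sequence[int] = (2016, 2017, 2018),
    photos_per_halfmonth: int = 3,
    photo_sd: float = 0.018,
    year_sd: float = 0.015,
    bear_id: str = "HC",
    seed=None,
) -> list[PhotoObservation]:
    """Photo series of one bear following a half-month ratio trajectory.

    Each (year, half-month) adds a Gaussian year effect (SD ``year_sd``) to
    the trajectory value; each photo adds independent noise (SD
    ``photo_sd``) and carries three replicate tracings. All photos score 1
    on every attribute ("Good").
    """
    rng = _rng(seed)
    traj = dict(trajectory) if trajectory is not None else dict(
        DEFAULT_SEASONAL_TRAJECTORY
    )
    photos: list[PhotoObservation] = []
    pid = 0
    for year in years:
        for (month, half), true_ratio in traj.items():
            level = true_ratio + rng.normal(0.0, year_sd)
            for _ in range(photos_per_halfmonth):
                day = int(rng.integers(1, 16)) if half == "early" else int(
                    rng.integers(16, 29)
                )
                ratio = max(level + rng.normal(0.0, photo_sd), 0.05)
                photos.append(
                    _photo_from_ratio(
                        f"S{pid:05d}", bear_id, dt.date(year, month, day),
                        ratio, rng,
                    )
                )
                pid += 1
    return photos


def generate_calibration_study(
    n_bears: int = 7,
    coupling: float = 0.77,
    ratio_mean: float = 0.711,
    ratio_sd: float = 0.05,
    photos_per_bear: int = 3,
    photo_sd: float = 0.005,
    allometry: AllometricModel = SHIRETOKO_REFERENCE_MODEL,
    seed=None,
) -> tuple[list[BearRecord], list[PhotoObservation]]:
    """Capture records plus near-capture photographs for calibration.

    Each bear is an adult female with a latent condition z ~ N(0, 1): her
    capture mass realizes BCI = z under ``allometry`` and her photographic
    TH:HTL is ``ratio_mean + ratio_sd * (c z + sqrt(1-c^2) e)``, so the
    bear-level correlation between the photographic ratio and BCI is the
    ``coupling``. Photographs fall within +/-3 days of the capture date and
    score 1 on every attribute.
    """
    rng = _rng(seed)
    records: list[BearRecord] = []
    photos: list[PhotoObservation] = []
    pid = 0
    for i in range(n_bears):
        z = rng.normal()
        length = float(rng.normal(143.0, 5.0))
        ln_mass = (
            allometry.slope * math.log(length) + allometry.intercept
            + allometry.resid_sd * z
        )
        year = int(rng.choice([2014, 2015, 2016]))
        capture = dt.date(year, int(rng.choice([8, 9, 10])),
                          int(rng.integers(4, 25)))
        bear_id = f"RF{i:02d}"
        records.append(
            BearRecord(
                bear_id=bear_id,
                sex=Sex.FEMALE,
                date=capture,
                body_mass=math.exp(ln_mass),
                body_length=length,
                age_years=int(rng.integers(5, 16)),
                source=Source.RESEARCH_CAPTURE,
            )
        )
        ratio_bear = ratio_mean + ratio_sd * (
            coupling * z + math.sqrt(max(0.0, 1 - coupling**2)) * rng.normal()
        )
        for _ in range(photos_per_bear):
            offset = int(rng.integers(-3, 4))
            ratio = max(ratio_bear + rng.normal(0.0, photo_sd), 0.05)
            photos.append(
                _photo_from_ratio(
                    f"C{pid:05d}", bear_id,
                    capture + dt.timedelta(days=offset), ratio, rng,
                )
            )
            pid += 1
    return records, photos
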