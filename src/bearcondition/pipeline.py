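"""End-to-end condition monitoring: photo selection, calibration, seasons.

The field workflow: photographs of an identifiable bear are scored and
filtered (:mod:`.photo_quality`), measured (:mod:`.geometry`), and reduced
to the TH:HTL ratio. Two analyses sit on top:

* Calibration — for bears that were also physically captured, photographs
  taken within a window (default +/- 3 days) of the capture date give a
  photographic TH:HTL, and the capture morphometrics give a BCI; BCI is
  regressed on TH:HTL so future photographs alone can estimate condition.
* Seasonal monitoring — for each half-month (days 1–15 / 16–end) with at
  least two eligible photographs, the median TH:HTL of the best
  photographs is the half-month evaluation value; evaluations from
  different years act as replicates in a one-way ANOVA across half-months.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .geometry import ratio_from_replicates
from .photo_quality import (
    PhotoScores,
    PostureCategory,
    RatioMethod,
    assign_posture_category,
    eligible_categories_for_method,
    passes_quality_filter,
)
from .precision import OneWayAnovaResult, one_way_anova_tukey, pearson_correlation

__all__ = [
    "PhotoObservation",
    "CalibrationModel",
    "RatioCalibration",
    "CalibrationResults",
    "BciPrediction",
    "predict_bci",
    "select_calibration_photos",
    "HalfMonthEvaluation",
    "halfmonth_evaluation",
    "seasonal_change_test",
]


@dataclass(frozen=True)
class PhotoObservation:
    """One scored photograph with its replicate TH and HTL tracings (px)."""

    photo_id: str
    bear_id: str
    date: dt.date
    scores: PhotoScores
    th_px: tuple[float, ...] = ()
    htl_px: tuple[float, ...] = ()

    @property
    def ratio(self) -> float:
        """TH:HTL from the replicate means."""
        return ratio_from_replicates(self.th_px, self.htl_px)

    @property
    def category(self) -> PostureCategory:
        if not passes_quality_filter(self.scores):
            return PostureCategory.UNUSABLE
        return assign_posture_category(self.scores)

    @property
    def quality_total(self) -> int:
        """Sum of attribute scores; lower = better photograph."""
        return self.scores.total


def _is_eligible(photo: PhotoObservation,
                 method: RatioMethod = RatioMethod.TH_HTL) -> bool:
    return (
        passes_quality_filter(photo.scores)
        and photo.category in eligible_categories_for_method(method)
    )


def select_calibration_photos(
    photos: Iterable[PhotoObservation],
    bear_id: str,
    capture_date: dt.date,
    window_days: int = 3,
    method: RatioMethod = RatioMethod.TH_HTL,
) -> list[PhotoObservation]:
    """Photographs of one bear usable for capture calibration.

    Keeps photographs of ``bear_id`` dated within ``window_days`` before or
    after the capture, passing the quality filter, and in a posture
    category eligible for ``method``. Fewer than two usable photographs is
    reported with a warning (the calibration pair should then be skipped).
    """
    window = dt.timedelta(days=window_days)
    selected = [
        p
        for p in photos
        if p.bear_id == bear_id
        and abs(p.date - capture_date) <= window
        and _is_eligible(p, method)
    ]
    if len(selected) < 2:
        warnings.warn(
            f"bear {bear_id}: only {len(selected)} usable photographs within "
            f"+/-{window_days} days of {capture_date}; calibration pair should "
            "be skipped"
        )
    return selected


@dataclass(frozen=True)
class CalibrationModel:
    """OLS of BCI on the photographic TH:HTL ratio."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    ratio_min: float
    ratio_max: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs at least 3 pairs")
        if not abs(self.r) <= 1.0:
            raise ValueError("|r| must be <= 1")


class BciPrediction(Sequence):
    """Predicted BCI values plus per-value extrapolation flags."""

    def __init__(self, values: np.ndarray, extrapolated: np.ndarray):
        self.values = values
        self.extrapolated = extrapolated

    def __len__(self):
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i]


class RatioCalibration:
    """Model linking the photographic TH:HTL ratio to capture-based BCI.

    Parameters are the paired observations; ``fit()`` performs the OLS of
    BCI on ratio and reports the Pearson correlation with its two-sided p.
    """

    def __init__(self, ratio, bci):
        ratio = np.asarray(ratio, dtype=float)
        bci = np.asarray(bci, dtype=float)
        if ratio.shape != bci.shape or ratio.ndim != 1:
            raise ValueError("ratio and bci must be equal-length 1-d arrays")
        if ratio.size < 3:
            raise ValueError("calibration needs at least 3 pairs")
        if np.ptp(ratio) == 0 or np.ptp(bci) == 0:
            raise ValueError("degenerate variance in calibration pairs")
        self.ratio = ratio
        self.bci = bci

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "RatioCalibration":
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    def fit(self) -> "CalibrationResults":
        import statsmodels.api as sm

        ols = sm.OLS(self.bci, sm.add_constant(self.ratio)).fit()
        r, p = pearson_correlation(self.ratio, self.bci)
        model = CalibrationModel(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            r=r,
            p_value=p,
            n=int(ols.nobs),
            ratio_min=float(self.ratio.min()),
            ratio_max=float(self.ratio.max()),
        )
        return CalibrationResults(self, model, ols)


class CalibrationResults:
    def __init__(self, calib: RatioCalibration, model: CalibrationModel, ols):
        self.data = calib
        self.model = model
        self._ols = ols

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    def predict(self, ratio) -> BciPrediction:
        return predict_bci(ratio, self.model)

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "TH:HTL -> BCI calibration (OLS)",
                f"  n pairs        {m.n}",
                f"  slope          {m.slope:9.3f}",
                f"  intercept      {m.intercept:9.3f}",
                f"  Pearson r      {m.r:9.3f}  (p = {m.p_value:.3f})",
                f"  R-squared      {self.rsquared:9.3f}",
                f"  ratio range    [{m.ratio_min:.3f}, {m.ratio_max:.3f}]",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.data.ratio, self.data.bci)
        xs = np.linspace(self.model.ratio_min, self.model.ratio_max, 20)
        ax.plot(xs, self.model.slope * xs + self.model.intercept, "k-")
        ax.set_xlabel("TH:HTL (photographic)")
        ax.set_ylabel("BCI (capture)")
        return ax


def predict_bci(ratio, model: CalibrationModel) -> BciPrediction:
    """Estimate BCI from TH:HTL; flags ratios outside the calibration range."""
    r = np.atleast_1d(np.asarray(ratio, dtype=float))
    values = model.slope * r + model.intercept
    extrapolated = (r < model.ratio_min) | (r > model.ratio_max)
    return BciPrediction(values, extrapolated)


@dataclass(frozen=True)
class HalfMonthEvaluation:
    """Median TH:HTL of the best photographs in one half-month of one year."""

    year: int
    month: int
    half: str  # "early" (days 1-15) or "late" (16-end)
    value: float
    n_photos: int

    @property
    def label(self) -> str:
        return f"{self.half}-{dt.date(2000, self.month, 1):%b}"


def _halfmonth_key(date: dt.date) -> tuple[int, int, str]:
    return (date.year, date.month, "early" if date.day <= 15 else "late")


def halfmonth_evaluation(
    photos: Iterable[PhotoObservation],
    min_photos: int = 2,
    best_n: Optional[int] = None,
    method: RatioMethod = RatioMethod.TH_HTL,
) -> list[HalfMonthEvaluation]:
    """Half-month evaluation values for one bear's photo series.

    Groups eligible photographs by (year, month, early/late), ranks them by
    total attribute score (ties broken by photo id), keeps the best
    ``best_n`` (all by default), and takes the median TH:HTL. Half-months
    with fewer than ``min_photos`` eligible photographs are omitted. Output
    order is chronological; the result does not depend on input order.
    """
    groups: dict[tuple[int, int, str], list[PhotoObservation]] = {}
    for p in photos:
        if not _is_eligible(p, method):
            continue
        groups.setdefault(_halfmonth_key(p.date), []).append(p)

    out = []
    for (year, month, half) in sorted(
        groups, key=lambda k: (k[0], k[1], 0 if k[2] == "early" else 1)
    ):
        g = sorted(groups[(year, month, half)],
                   key=lambda p: (p.quality_total, p.photo_id))
        if len(g) < min_photos:
            continue
        if best_n is not None:
            g = g[: max(best_n, min_photos)]
        value = float(np.median([p.ratio for p in g]))
        out.append(HalfMonthEvaluation(year, month, half, value, len(g)))
    return out


def seasonal_change_test(
    evaluations: Sequence[HalfMonthEvaluation],
) -> OneWayAnovaResult:
    """One-way ANOVA (with Tukey pairs) of evaluation values across half-months.

    Yearly evaluation values are the replicates within each half-month
    level; levels observed in fewer than 2 years are excluded with a
    warning. Eight half-months with three yearly replicates give the
    (7, 16) df layout.
    """
    groups: dict[str, list[float]] = {}
    for ev in evaluations:
        groups.setdefault(ev.label, []).append(ev.value)
    dropped = [lab for lab, v in groups.items() if len(v) < 2]
    if dropped:
        warnings.warn(
            f"half-months with <2 yearly evaluations excluded: {dropped}"
        )
        groups = {lab: v for lab, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 half-month levels with replicates")
    return one_way_anova_tukey(groups)
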