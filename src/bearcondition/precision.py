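"""Replicate-measurement precision and the study's statistical tests.

Precision framework: a measurement repeated n times has coefficient of
variation CV = 100 * SD / mean (sample SD, n-1 denominator). Treating the
SD of a long replicate series (50 tracings of one photograph) as the
population SD, the standard error of a mean of n measurements is SD/sqrt(n);
the minimum replicate count is the smallest n whose SE drops below a
threshold chosen so measurement error cannot affect the second decimal
place of a ratio (SE < 0.0025).

Statistical comparisons:

* Feltz–Miller asymptotic chi-square test for equality of coefficients of
  variation across k groups.
* Pearson correlation with the two-sided t test.
* One-way ANOVA with Tukey–Kramer (unbalanced) multiple comparisons.
* Two-way ANOVA with interaction using sequential (Type I) sums of squares.
  Term degrees of freedom are obtained from design-matrix ranks, so an
  empty factor-combination cell reduces the interaction df exactly as R's
  ``lm`` does by dropping aliased coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecisionSummary",
    "coefficient_of_variation",
    "se_at_n",
    "min_measurements",
    "CvEqualityTest",
    "cv_equality_test",
    "pearson_correlation",
    "OneWayAnovaResult",
    "one_way_anova_tukey",
    "two_way_anova",
    "SE_THRESHOLD",
]

#: SE bound below which measurement error cannot affect the second decimal
#: place of a ratio.
SE_THRESHOLD = 0.0025


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 * SD(n-1) / mean. Requires mean > 0, n >= 2."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV is undefined for nonpositive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def se_at_n(population_sd: float, n: int) -> float:
    """Standard error of a mean of n measurements: sd / sqrt(n)."""
    if population_sd < 0:
        raise ValueError("sd must be nonnegative")
    if n < 1:
        raise ValueError("n must be a positive integer")
    return population_sd / math.sqrt(n)


def min_measurements(population_sd: float,
                     threshold: float = SE_THRESHOLD) -> int:
    """Smallest n with sd/sqrt(n) strictly below the threshold."""
    if population_sd < 0 or threshold <= 0:
        raise ValueError("sd must be >= 0 and threshold > 0")
    if population_sd == 0:
        return 1
    q = (population_sd / threshold) ** 2
    n = int(math.floor(q)) + 1  # strict inequality: n > (sd/thr)^2
    return max(n, 1)


@dataclass(frozen=True)
class PrecisionSummary:
    """Mean / SD / CV of a replicate series and SE at chosen replicate counts."""

    mean: float
    sd: float
    cv: float  # percent
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "PrecisionSummary":
        x = np.asarray(values, dtype=float)
        return cls(
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)),
            cv=coefficient_of_variation(x),
            n=int(x.size),
        )

    def se_at(self, n: int) -> float:
        """SE of a mean of n measurements, with this series' SD as population SD."""
        return se_at_n(self.sd, n)

    def min_measurements(self, threshold: float = SE_THRESHOLD) -> int:
        return min_measurements(self.sd, threshold)


class CvEqualityTest(NamedTuple):
    statistic: float
    df: int
    p_value: float


def cv_equality_test(cvs: Sequence[float], ns: Sequence[int]) -> CvEqualityTest:
    """Feltz–Miller asymptotic test for equality of k coefficients of variation.

    ``cvs`` may be given in percent or as fractions; values are normalized
    internally (any CV above 1 is taken as percent), so the statistic is
    scale-invariant. With weights m_i = n_i - 1 and pooled CV
    c = sum(m_i c_i) / sum(m_i), the statistic

        D = sum m_i (c_i - c)^2 / (c^2 (0.5 + c^2))

    is asymptotically chi-square with k - 1 df under CV equality.
    """
    c = np.asarray(cvs, dtype=float)
    n = np.asarray(ns, dtype=float)
    if c.size != n.size or c.size < 2:
        raise ValueError("need k >= 2 matching CVs and sample sizes")
    if np.any(c <= 0):
        raise ValueError("CVs must be strictly positive")
    if np.any(n < 2):
        raise ValueError("each sample size must be at least 2")
    if np.any(c > 1.0):  # given in percent
        c = c / 100.0
    m = n - 1.0
    pooled = float(np.sum(m * c) / np.sum(m))
    d = float(np.sum(m * (c - pooled) ** 2) / (pooled**2 * (0.5 + pooled**2)))
    df = int(c.size - 1)
    return CvEqualityTest(d, df, float(stats.chi2.sf(d, df)))


class PearsonCorrelation(NamedTuple):
    r: float
    p_value: float


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonCorrelation:
    """Sample Pearson r with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return PearsonCorrelation(float(res.statistic), float(res.pvalue))


@dataclass
class OneWayAnovaResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    tukey: pd.DataFrame  # pairwise Tukey-Kramer table

    def pairwise_p(self, group1: str, group2: str) -> float:
        t = self.tukey
        key = {group1, group2}
        for _, row in t.iterrows():
            if {row["group1"], row["group2"]} == key:
                return float(row["p_adj"])
        raise KeyError(f"no pair {group1}/{group2} in Tukey table")


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]]) -> OneWayAnovaResult:
    """One-way ANOVA with Tukey–Kramer HSD pairwise comparisons.

    Handles unbalanced groups; each group needs at least 2 observations.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")

    f_stat, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    codes = np.concatenate([np.full(a.size, g, dtype=object)
                            for g, a in zip(labels, arrays)])
    hsd = pairwise_tukeyhsd(values, codes)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper",
                 "reject"],
    )
    for col in ("meandiff", "p_adj", "lower", "upper"):
        tukey[col] = tukey[col].astype(float)
    return OneWayAnovaResult(float(f_stat), k - 1, n - k, float(p), tukey)


def _rss_and_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def two_way_anova(response: Sequence[float], factor_a: Sequence,
                  factor_b: Sequence) -> pd.DataFrame:
    """Two-way ANOVA with interaction, sequential (Type I) sums of squares.

    Factors enter in the order given (A, then B, then A:B). Returns a table
    indexed by term with columns ``sum_sq``, ``df``, ``F`` and ``PR(>F)``.
    Empty cells are tolerated: each term's df is the rank gained when its
    columns enter the design, so a missing factor combination reduces the
    interaction df rather than failing.
    """
    y = np.asarray(response, dtype=float)
    a = pd.Categorical(np.asarray(factor_a, dtype=object))
    b = pd.Categorical(np.asarray(factor_b, dtype=object))
    if y.size != len(a) or y.size != len(b):
        raise ValueError("response and factors must have equal length")
    if len(a.categories) < 2 or len(b.categories) < 2:
        raise ValueError("each factor needs at least 2 levels")

    n = y.size
    intercept = np.ones((n, 1))
    dummies_a = pd.get_dummies(a, dtype=float).to_numpy()
    dummies_b = pd.get_dummies(b, dtype=float).to_numpy()
    cell = pd.get_dummies(
        pd.Series([f"{x}\x1f{z}" for x, z in zip(a, b)]), dtype=float
    ).to_numpy()

    blocks = [intercept, dummies_a, dummies_b, cell]
    rss, rank, design = [], [], np.empty((n, 0))
    for blk in blocks:
        design = np.hstack([design, blk])
        r, rk = _rss_and_rank(design, y)
        rss.append(r)
        rank.append(rk)

    ss = [rss[i] - rss[i + 1] for i in range(3)]
    df = [rank[i + 1] - rank[i] for i in range(3)]
    df_resid = n - rank[3]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    if any(d == 0 for d in df):
        raise ValueError("a model term is inestimable (aliased factor levels)")
    mse = rss[3] / df_resid

    rows = {}
    for name, s, d in zip(("factor_a", "factor_b", "interaction"), ss, df):
        f = (s / d) / mse
        rows[name] = {"sum_sq": s, "df": d, "F": f,
                      "PR(>F)": float(stats.f.sf(f, d, df_resid))}
    rows["residual"] = {"sum_sq": rss[3], "df": df_resid, "F": np.nan,
                        "PR(>F)": np.nan}
    return pd.DataFrame(rows).T[["sum_sq", "df", "F", "PR(>F)"]]
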