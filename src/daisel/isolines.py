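"""DAI isoline thresholds and the four-group adaptation classification.

In the (stressed yield, control yield) plane a constant DAI traces the
hyperbola Yuc = C1 * Ybar_cv * Ybar_uc / Ycv. Threshold constants are
obtained by evaluating the DAI at the point lying k standard deviations
above both grand means:

    C1_k = (Ybar_cv + k*s_cv) * (Ybar_uc + k*s_uc) / (Ybar_cv * Ybar_uc)

so C1_0 = 1 always, and C1 increases with k whenever both SDs are positive.
Genotypes are then classified by which isoline band their DAI falls in:
very well-adapted (DAI >= C1_2), well-adapted (C1_1 <= DAI < C1_2), adapted
(C1_0 <= DAI < C1_1), unadapted (DAI < C1_0). "Above the isoline" is read
as a closed lower boundary so the four classes are exhaustive.

The product functional form of C1 is an inference from its observable
behaviour (level 0 equals 1 in every year; levels 1 and 2 scale with the
yield coefficients of variation); it is isolated here so it can be swapped
if the originating breeding program publishes the exact function.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "IsolineThresholds",
    "AdaptationClass",
    "c1_constants",
    "isoline_points",
    "classify_genotypes",
    "multi_year_class_summary",
]


class AdaptationClass(str, Enum):
    VERY_WELL_ADAPTED = "very_well_adapted"
    WELL_ADAPTED = "well_adapted"
    ADAPTED = "adapted"
    UNADAPTED = "unadapted"
    UNCLASSIFIED = "unclassified"  # missing DAI only


# ordered worst → best for monotonicity checks
CLASS_ORDER = [
    AdaptationClass.UNADAPTED,
    AdaptationClass.ADAPTED,
    AdaptationClass.WELL_ADAPTED,
    AdaptationClass.VERY_WELL_ADAPTED,
]


@dataclass(frozen=True)
class IsolineThresholds:
    """C1 threshold constants and the moments they were derived from."""

    levels: tuple[float, ...]
    c1: tuple[float, ...]
    mean_cv: float
    sd_cv: float
    mean_uc: float
    sd_uc: float
    year: int | None = None

    def c1_at(self, level: float) -> float:
        return self.c1[self.levels.index(level)]


def c1_constants(
    y_cv: np.ndarray,
    y_uc: np.ndarray,
    levels: tuple[float, ...] = (0.0, 1.0, 2.0),
    year: int | None = None,
    population_sd: bool = False,
) -> IsolineThresholds:
    """DAI threshold constants at the requested SD levels.

    Means and SDs are computed from the supplied yield vectors (BLUP scale;
    sample SD with n−1 denominator unless ``population_sd``). Both means
    must be positive.
    """
    cv = np.asarray(y_cv, dtype=float)
    uc = np.asarray(y_uc, dtype=float)
    cv, uc = cv[np.isfinite(cv)], uc[np.isfinite(uc)]
    if cv.size == 0 or uc.size == 0:
        raise ValueError("empty yield vector")
    m_cv, m_uc = float(np.mean(cv)), float(np.mean(uc))
    if m_cv <= 0 or m_uc <= 0:
        raise ValueError("grand means must be positive")
    ddof = 0 if population_sd else 1
    s_cv = float(np.std(cv, ddof=ddof)) if cv.size > ddof else 0.0
    s_uc = float(np.std(uc, ddof=ddof)) if uc.size > ddof else 0.0
    c1 = tuple(
        (m_cv + k * s_cv) * (m_uc + k * s_uc) / (m_cv * m_uc) for k in levels
    )
    return IsolineThresholds(
        levels=tuple(levels), c1=c1, mean_cv=m_cv, sd_cv=s_cv,
        mean_uc=m_uc, sd_uc=s_uc, year=year,
    )


def isoline_points(
    c1: float, mean_cv: float, mean_uc: float, grid: np.ndarray
) -> pd.DataFrame:
    """Points on the DAI = C1 level set, for overlaying on yield scatter plots."""
    g = np.asarray(grid, dtype=float)
    if c1 <= 0:
        raise ValueError("C1 must be positive")
    if np.any(g <= 0):
        raise ValueError("grid values must be positive")
    return pd.DataFrame({"Ycv": g, "Yuc": c1 * mean_cv * mean_uc / g})


def classify_genotypes(
    dai: pd.Series, thresholds: IsolineThresholds
) -> pd.Series:
    """Assign each genotype's DAI to one of the four adaptation classes.

    Boundaries are assigned upward (a DAI exactly on an isoline gets the
    better class). Missing DAI values are reported as ``unclassified``.
    """
    c0 = thresholds.c1_at(0.0)
    c1 = thresholds.c1_at(1.0)
    c2 = thresholds.c1_at(2.0)

    def one(v: float) -> str:
        if not np.isfinite(v):
            return AdaptationClass.UNCLASSIFIED.value
        if v >= c2:
            return AdaptationClass.VERY_WELL_ADAPTED.value
        if v >= c1:
            return AdaptationClass.WELL_ADAPTED.value
        if v >= c0:
            return AdaptationClass.ADAPTED.value
        return AdaptationClass.UNADAPTED.value

    return dai.map(one)


def multi_year_class_summary(per_year: dict[int, pd.Series]) -> pd.DataFrame:
    """Genotype × year class table with persistence counts for the top class.

    ``total_top`` counts years classified very well-adapted; ``consecutive_top``
    is the longest run of consecutive years in that class.
    """
    if not per_year:
        raise ValueError("no classified years")
    years = sorted(per_year)
    wide = pd.DataFrame({y: per_year[y] for y in years})
    top = AdaptationClass.VERY_WELL_ADAPTED.value

    def longest_run(row) -> int:
        best = run = 0
        for y in years:
            run = run + 1 if row[y] == top else 0
            best = max(best, run)
        return best

    wide["total_top"] = (wide[years] == top).sum(axis=1)
    wide["consecutive_top"] = wide.apply(longest_run, axis=1)
    wide.index.name = "genotype_id"
    return wide
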