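"""Yield-data curation: minimum-yield filter, MAD outlier screen, normality.

Single-plant biomass yields are right-skewed, with a spike of very small
plants (failed establishment, filler competition). Curation therefore (1)
drops implausibly small yields below a fixed threshold, then (2) flags
outliers by robust distance from the median in units of the median absolute
deviation (MAD), and (3) reports Shapiro-Wilk normality diagnostics and QQ
coordinates per year × treatment group — for reporting only, never as a
gate: the downstream mixed model relies on BLUP shrinkage rather than on a
normalising transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PlotRecord

log = logging.getLogger("daisel")

__all__ = [
    "CurationReport",
    "filter_min_yield",
    "mad_outlier_mask",
    "shapiro_wilk",
    "qq_coordinates",
    "curate",
]


@dataclass
class CurationReport:
    """Bookkeeping for one curation run: counts and per-group diagnostics.

    Invariant: ``n_input == n_retained + n_below_threshold + n_outliers``.
    """

    n_input: int = 0
    n_below_threshold: int = 0
    n_outliers: int = 0
    n_retained: int = 0
    shapiro: pd.DataFrame = field(default_factory=pd.DataFrame)
    retained_keys: list[tuple] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_input == self.n_retained + self.n_below_threshold + self.n_outliers


def filter_min_yield(records: list[PlotRecord], threshold: float = 50.0) -> list[PlotRecord]:
    """Drop records whose dry yield is strictly below ``threshold`` grams.

    The boundary is kept: "below 50 g" is read strictly, so a 50 g plant
    survives. All records must carry a dry yield.
    """
    for r in records:
        if r.dry_yield is None:
            raise ValueError(f"record at {r.position_key} has no dry_yield")
    return [r for r in records if r.dry_yield >= threshold]


def mad_outlier_mask(
    values: np.ndarray,
    cutoff: float = 6.0,
    scale_constant: float = 1.4826,
) -> np.ndarray:
    """Flag values whose MAD-scaled distance from the median exceeds ``cutoff``.

    The robust distance is::

        absMADAway_i = |x_i - median(x)| / (scale_constant * median_j |x_j - median(x)|)

    and ``mask[i]`` is True iff ``absMADAway_i > cutoff``. The default scale
    constant 1.4826 makes the denominator a consistent estimate of the normal
    standard deviation; 1.0 gives the raw-MAD convention.

    If the MAD is zero (more than half the values tied) the distance is
    undefined: nothing is flagged and a warning is logged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or np.sum(np.isfinite(x)) < 3:
        raise ValueError("need a 1-D vector with at least 3 finite values")
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0:
        log.warning("MAD is zero; outlier distance undefined, flagging nothing")
        return np.zeros_like(x, dtype=bool)
    away = np.abs(x - med) / (scale_constant * mad)
    mask = away > cutoff
    mask[~np.isfinite(x)] = False
    return mask


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston approximation), for 3 ≤ n ≤ 5000."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={x.size}")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def qq_coordinates(values: np.ndarray) -> pd.DataFrame:
    """Normal QQ-plot coordinates at plotting positions (i − 0.5)/n.

    Returns a two-column frame (theoretical standard-normal quantile,
    ordered sample value), sorted ascending, ready for CSV export.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values for a QQ plot")
    p = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": stats.norm.ppf(p), "observed": x})


def curate(
    records: list[PlotRecord],
    min_yield: float = 50.0,
    mad_cutoff: float = 6.0,
    mad_scale_constant: float = 1.4826,
    group_by: tuple[str, ...] = ("year", "treatment"),
) -> tuple[list[PlotRecord], CurationReport]:
    """Full curation pass: min-yield filter, then per-group MAD screen.

    Filler records are excluded up front (they carry no genotype statistics).
    The order is fixed — threshold first, outlier screen on the filtered
    data — because the screen's median and MAD should not be dragged by the
    sub-threshold spike. Outliers are screened within each ``group_by``
    group (default year × treatment) so level shifts between environments
    are not mistaken for outliers.
    """
    study = [r for r in records if not r.is_filler]
    report = CurationReport(n_input=len(study))

    kept = filter_min_yield(study, min_yield)
    report.n_below_threshold = len(study) - len(kept)

    def group_key(r: PlotRecord) -> tuple:
        return tuple(getattr(r, g) for g in group_by)

    groups: dict[tuple, list[PlotRecord]] = {}
    for r in kept:
        groups.setdefault(group_key(r), []).append(r)

    retained: list[PlotRecord] = []
    shapiro_rows = []
    for key in sorted(groups, key=str):
        grp = groups[key]
        y = np.array([r.dry_yield for r in grp])
        if y.size >= 3:
            mask = mad_outlier_mask(y, mad_cutoff, mad_scale_constant)
        else:
            mask = np.zeros(y.size, dtype=bool)
        clean = [r for r, out in zip(grp, mask) if not out]
        report.n_outliers += int(mask.sum())
        retained.extend(clean)
        if len(clean) >= 3:
            w, p = shapiro_wilk(np.array([r.dry_yield for r in clean]))
            shapiro_rows.append(dict(zip(group_by, key)) | {"W": w, "p": p, "n": len(clean)})

    report.n_retained = len(retained)
    report.retained_keys = [r.position_key for r in retained]
    report.shapiro = pd.DataFrame(shapiro_rows)
    report.validate()
    return retained, report
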