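"""Drought adaptation index (DAI) and nine classical stress-tolerance indices.

All indices are functions of a genotype's BLUP-predicted yield under stress
(Ys, the covered/drought treatment CV) and non-stress (Yp, the uncovered
control UC) and of the corresponding grand means over genotypes (Ybar_s,
Ybar_p), computed separately per year:

    DAI = (Ys * Yp) / (Ybar_s * Ybar_p)
    SSI = (1 - Ys/Yp) / (1 - Ybar_s/Ybar_p)
    TOL = Yp - Ys                      MP  = (Yp + Ys) / 2
    GMP = sqrt(Ys * Yp)                STI = Ys * Yp / Ybar_p**2
    YSI = Ys / Yp                      YI  = Ys / Ybar_p
    HM  = 2 Ys Yp / (Ys + Yp)          DSI = (Ys - Yp) / Yp

The DAI is scale-free — multiplying every stressed yield by one constant and
every control yield by another leaves it unchanged — and equals 1 for a
genotype at both grand means. Useful identities (exercised in tests):
GMP² = MP² − (TOL/2)², DSI = YSI − 1, DAI = STI · Ybar_p / Ybar_s.

A geometric-mean variant of the DAI (square root of the ratio) is available
behind ``sqrt=True``; the product form is the default. Likewise YI is
printed here with the non-stress grand mean in the denominator (Ys/Ybar_p);
the conventional stressed-mean form Ys/Ybar_s is available via
``yi_stress_mean=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BlupTable, Treatment

log = logging.getLogger("daisel")

__all__ = [
    "IndexInputs",
    "compute_dai",
    "compute_indices",
    "index_table",
    "index_correlation_matrix",
    "dai_year_stability",
    "INDEX_NAMES",
]

INDEX_NAMES = ("DAI", "SSI", "TOL", "MP", "GMP", "STI", "YSI", "YI", "HM", "DSI")


@dataclass(frozen=True)
class IndexInputs:
    """Per-genotype yields and grand means for one year (grams)."""

    Ys: float  # stress (CV) BLUP-predicted yield
    Yp: float  # non-stress (UC) BLUP-predicted yield
    Ybar_s: float
    Ybar_p: float

    def __post_init__(self) -> None:
        if self.Ybar_s <= 0 or self.Ybar_p <= 0:
            raise ValueError("grand means must be positive")


def compute_dai(inp: IndexInputs, sqrt: bool = False) -> float:
    """Drought adaptation index for one genotype-year."""
    dai = (inp.Ys * inp.Yp) / (inp.Ybar_s * inp.Ybar_p)
    return float(np.sqrt(dai)) if sqrt else float(dai)


def compute_indices(
    inp: IndexInputs, dai_sqrt: bool = False, yi_stress_mean: bool = False
) -> dict[str, float]:
    """All ten indices for one genotype-year; undefined entries become NaN."""
    ys, yp, mbs, mbp = inp.Ys, inp.Yp, inp.Ybar_s, inp.Ybar_p
    out: dict[str, float] = {}
    out["DAI"] = compute_dai(inp, sqrt=dai_sqrt)
    if yp > 0 and mbs != mbp:
        out["SSI"] = (1 - ys / yp) / (1 - mbs / mbp)
    else:
        out["SSI"] = np.nan
        if mbs == mbp:
            log.warning("SSI undefined: stress and non-stress grand means equal")
    out["TOL"] = yp - ys
    out["MP"] = (yp + ys) / 2
    out["GMP"] = float(np.sqrt(ys * yp)) if ys * yp >= 0 else np.nan
    out["STI"] = ys * yp / mbp**2
    out["YSI"] = ys / yp if yp > 0 else np.nan
    out["YI"] = ys / (mbs if yi_stress_mean else mbp)
    out["HM"] = 2 * ys * yp / (ys + yp) if ys + yp > 0 else np.nan
    out["DSI"] = (ys - yp) / yp if yp > 0 else np.nan
    return out


def index_table(
    blups: BlupTable, dai_sqrt: bool = False, yi_stress_mean: bool = False
) -> pd.DataFrame:
    """Per-genotype, per-year index table from a BLUP matrix.

    Each year needs both a CV and a UC environment column; genotypes missing
    either yield carry NaN for that year's indices. Grand means are taken
    over genotypes with an observed value in that column, mirroring the
    per-environment fits.
    """
    df = blups.to_frame()
    env_by_year: dict[int, dict[str, str]] = {}
    for env in blups.environments:
        env_by_year.setdefault(env.year, {})[env.treatment.value] = env.label

    rows = []
    for year in sorted(env_by_year):
        pair = env_by_year[year]
        if Treatment.CV.value not in pair or Treatment.UC.value not in pair:
            log.warning("year %s lacks a CV/UC pair; skipped", year)
            continue
        ys_col = df[pair["CV"]]
        yp_col = df[pair["UC"]]
        mbs, mbp = float(ys_col.mean()), float(yp_col.mean())
        for gid in df.index:
            ys, yp = ys_col[gid], yp_col[gid]
            if np.isnan(ys) or np.isnan(yp):
                vals = {k: np.nan for k in INDEX_NAMES}
            else:
                vals = compute_indices(
                    IndexInputs(float(ys), float(yp), mbs, mbp),
                    dai_sqrt=dai_sqrt,
                    yi_stress_mean=yi_stress_mean,
                )
            rows.append({"genotype_id": gid, "year": year} | vals)
    return pd.DataFrame(rows, columns=["genotype_id", "year", *INDEX_NAMES])


def index_correlation_matrix(table: pd.DataFrame, year: int) -> pd.DataFrame:
    """Pearson correlations among the ten indices for one year.

    Complete-observation policy: only genotypes with every index present
    enter. A constant column yields NaN correlations with a warning.
    """
    sub = table.loc[table["year"] == year, list(INDEX_NAMES)].dropna()
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 complete genotypes for year {year}")
    for name in INDEX_NAMES:
        if np.isclose(sub[name].std(ddof=1), 0.0):
            log.warning("index %s is constant in %s; correlations undefined", name, year)
    return sub.corr(method="pearson")


def dai_year_stability(table: pd.DataFrame) -> pd.DataFrame:
    """Year × year Pearson correlation of DAI over shared genotypes.

    Each pair of years is correlated on the genotypes with a DAI in both;
    pairs sharing fewer than 3 genotypes get NaN.
    """
    wide = table.pivot(index="genotype_id", columns="year", values="DAI")
    years = list(wide.columns)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    out = pd.DataFrame(np.eye(len(years)), index=years, columns=years)
    for i, a in enumerate(years):
        for b in years[i + 1 :]:
            pair = wide[[a, b]].dropna()
            r = pair[a].corr(pair[b]) if len(pair) >= 3 else np.nan
            out.loc[a, b] = out.loc[b, a] = r
    return out
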