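"""AMMI: additive main effects + multiplicative interaction decomposition.

The genotype × environment matrix of BLUP-predicted yields is modelled as

    y_ij = mu + g_i + e_j + sum_k lambda_k u_ik v_jk + rho_ij

ANOVA partitions the corrected total sum of squares into genotype main
effects (SS_G = e * sum_i (gbar_i - grand)^2), environment main effects
(SS_E = g * sum_j (ebar_j - grand)^2) and interaction (SS_GEI); the SVD of
the double-centred residual z_ij = y_ij - gbar_i - ebar_j + grand then
splits SS_GEI into interaction principal component axes (IPCA), with
lambda_k^2 the SS captured by axis k. Genotype and environment scores are
scaled symmetrically by sqrt(lambda_k), so the squared scores on each side
of an axis sum to lambda_k.

Axis degrees of freedom follow Gollob: df_k = g + e - 1 - 2k. Because the
input is a matrix of predictions (one number per cell, no plot-level
replicate error), F ratios are formed against internal mean squares:
genotypes and environments against the interaction MS, each IPCA against
the AMMI residual MS (interaction SS minus the retained axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BlupTable

log = logging.getLogger("daisel")

__all__ = ["GEMatrix", "AmmiResult", "impute_column_min", "ammi_decompose", "ammi_biplot_coords"]


@dataclass
class GEMatrix:
    """A complete genotype × environment yield matrix with its margins."""

    genotypes: list[str]
    environments: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise ValueError("GEMatrix must be complete (no missing cells)")
        if self.values.shape != (len(self.genotypes), len(self.environments)):
            raise ValueError("matrix shape does not match labels")

    @property
    def genotype_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def environment_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotypes, columns=self.environments)


def impute_column_min(table: BlupTable) -> GEMatrix:
    """Complete a BLUP matrix by imputing each missing cell with its
    environment-column minimum.

    Keeps imputed values inside the observed range of each environment; the
    positions imputed are logged. A fully missing column is an error.
    """
    values = table.values.copy()
    for j, env in enumerate(table.environments):
        col = values[:, j]
        missing = np.isnan(col)
        if missing.all():
            raise ValueError(f"environment {env.label} has no observed values")
        if missing.any():
            col_min = np.nanmin(col)
            for i in np.flatnonzero(missing):
                log.info(
                    "imputed %s / %s with column minimum %.4f",
                    table.genotypes[i], env.label, col_min,
                )
            col[missing] = col_min
    return GEMatrix(
        genotypes=list(table.genotypes),
        environments=[e.label for e in table.environments],
        values=values,
    )


@dataclass
class AmmiResult:
    anova: pd.DataFrame  # source, df, SS, MS, F, p
    singular_values: np.ndarray  # all min(g,e)-1 of them
    genotype_scores: pd.DataFrame  # index genotype, columns IPCA1..K + mean
    environment_scores: pd.DataFrame
    interaction_ss: float
    axis_ss_fraction: np.ndarray  # lambda_k^2 / SS_GEI per retained axis
    grand_mean: float


def ammi_decompose(m: GEMatrix, k_max: int = 2) -> AmmiResult:
    """Two-way ANOVA plus SVD partition of the interaction.

    ``k_max`` is the number of IPCA axes given their own ANOVA rows; the
    remainder is pooled into the AMMI residual.
    """
    y = m.values
    g, e = y.shape
    if g < 3 or e < 3:
        raise ValueError("need at least 3 genotypes and 3 environments")
    max_axes = min(g, e) - 1
    if not 1 <= k_max <= max_axes:
        raise ValueError(f"k_max must be in [1, {max_axes}]")

    grand = m.grand_mean
    gdev = m.genotype_means - grand
    edev = m.environment_means - grand
    ss_g = e * float(np.sum(gdev**2))
    ss_e = g * float(np.sum(edev**2))

    z = y - m.genotype_means[:, None] - m.environment_means[None, :] + grand
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    s = s[:max_axes]
    u = u[:, :max_axes]
    v = vt[:max_axes].T
    # SVD signs are arbitrary: flip each axis so the environment score with
    # the largest magnitude is positive (published tables may differ by a
    # global sign per axis).
    for k in range(max_axes):
        if v[np.argmax(np.abs(v[:, k])), k] < 0:
            u[:, k] *= -1
            v[:, k] *= -1
    ss_gei = float(np.sum(z**2))

    gscores = u * np.sqrt(s)  # (g, axes)
    escores = v * np.sqrt(s)

    def fratio(ms_num: float, ms_den: float) -> float:
        # a zero denominator MS (perfectly additive or exactly low-rank
        # input) leaves the F ratio undefined
        return ms_num / ms_den if ms_den > 0 else np.nan

    df_g, df_e, df_gei = g - 1, e - 1, (g - 1) * (e - 1)
    ms_gei = ss_gei / df_gei
    rows = [
        ("Genotypes", df_g, ss_g, ss_g / df_g, fratio(ss_g / df_g, ms_gei)),
        ("Environments", df_e, ss_e, ss_e / df_e, fratio(ss_e / df_e, ms_gei)),
        ("Interactions", df_gei, ss_gei, ms_gei, np.nan),
    ]
    gollob = [g + e - 1 - 2 * k for k in range(1, k_max + 1)]
    ss_axes = s[:k_max] ** 2
    resid_ss = max(ss_gei - float(np.sum(ss_axes)), 0.0)
    resid_df = df_gei - sum(gollob)
    ms_resid = resid_ss / resid_df if resid_df > 0 else np.nan
    for k, (df_k, ss_k) in enumerate(zip(gollob, ss_axes), start=1):
        rows.append((f"IPCA {k}", df_k, float(ss_k), float(ss_k) / df_k,
                     fratio(float(ss_k) / df_k, ms_resid) if resid_df > 0 else np.nan))
    rows.append(("Residuals", resid_df, resid_ss, ms_resid, np.nan))

    anova = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F"])
    anova["p"] = [
        float(stats.f.sf(f, int(d), resid_df if src.startswith("IPCA") else df_gei))
        if np.isfinite(f) else np.nan
        for src, d, f in zip(anova["source"], anova["df"], anova["F"])
    ]

    gs = pd.DataFrame(
        gscores[:, :k_max], index=pd.Index(m.genotypes, name="genotype_id"),
        columns=[f"IPCA{k}" for k in range(1, k_max + 1)],
    )
    gs.insert(0, "mean", m.genotype_means)
    es = pd.DataFrame(
        escores[:, :k_max], index=pd.Index(m.environments, name="environment"),
        columns=[f"IPCA{k}" for k in range(1, k_max + 1)],
    )
    es.insert(0, "mean", m.environment_means)

    return AmmiResult(
        anova=anova,
        singular_values=s,
        genotype_scores=gs,
        environment_scores=es,
        interaction_ss=ss_gei,
        axis_ss_fraction=ss_axes / ss_gei if ss_gei > 0 else np.zeros(k_max),
        grand_mean=grand,
    )


def ammi_biplot_coords(res: AmmiResult, view: str = "mean_vs_ipca1") -> pd.DataFrame:
    """Biplot point sets for genotypes and environments.

    Views: ``mean_vs_ipca1`` and ``mean_vs_ipca2`` put mean yield on x and
    the axis score on y; ``ipca1_vs_ipca2`` plots the first two axis scores.
    """
    pairs = {
        "mean_vs_ipca1": ("mean", "IPCA1"),
        "ipca1_vs_ipca2": ("IPCA1", "IPCA2"),
        "mean_vs_ipca2": ("mean", "IPCA2"),
    }
    if view not in pairs:
        raise ValueError(f"unknown view {view!r}")
    xcol, ycol = pairs[view]
    frames = []
    for kind, scores in (("genotype", res.genotype_scores), ("environment", res.environment_scores)):
        if ycol not in scores.columns or xcol not in scores.columns:
            raise ValueError(f"view {view!r} needs axis column {ycol}; rerun with more axes")
        frames.append(pd.DataFrame({
            "entity": scores.index, "kind": kind,
            "x": scores[xcol].to_numpy(), "y": scores[ycol].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
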