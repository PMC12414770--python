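"""One-way random-genotype mixed model: REML variance components and BLUP.

For each year × treatment environment the model is

    y_ij = mu + g_i + e_ij,   g_i ~ N(0, Vg),  e_ij ~ N(0, Ve)

fitted by REML, with the genotype effect predicted by its BLUP

    g_hat_i = Vg / (Vg + Ve / n_i) * (ybar_i - mu_hat)

so every genotype mean is shrunk toward the grand mean in proportion to its
replication and the signal-to-noise ratio. Yield-scale predictions are
mu_hat + g_hat_i; repeatability for clonally replicated material is
R = Vg / Vp with Vp = Vg + Ve.

REML is computed by concentrating the likelihood down to the single
variance ratio gamma = Vg / Ve. For fixed gamma the per-genotype marginal
covariance is Ve * (I + gamma * J), whose inverse and determinant are
closed-form, so the profiled criterion

    (N - 1) log sigma2_hat(gamma) + sum_i log(1 + gamma n_i)
      + log sum_i n_i / (1 + gamma n_i)

is minimised by a bounded deterministic scalar search (no random starts;
tolerance 1e-8 on the ratio). On balanced data the optimum coincides with
the one-way ANOVA estimator Vg = (MSG - MSE) / r truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import BlupTable, Environment, PlotRecord

__all__ = [
    "VarianceComponents",
    "GenotypePrediction",
    "fit_random_genotype",
    "repeatability",
    "build_blup_table",
    "fit_environments",
]


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components for one year × treatment fit (units g, g²)."""

    Vg: float
    Ve: float
    mu: float
    n_obs: int
    n_genotypes: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.Vg < 0 or self.Ve < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def Vp(self) -> float:
        """Total phenotypic variance Vg + Ve (plot basis)."""
        return self.Vg + self.Ve

    @property
    def R(self) -> float:
        return repeatability(self)


@dataclass(frozen=True)
class GenotypePrediction:
    genotype_id: str
    blup_effect: float  # deviation from the grand mean, g
    predicted_value: float  # mu + blup_effect, g
    n_obs: int


def repeatability(vc: VarianceComponents, mean_basis: bool = False) -> float:
    """Repeatability R = Vg / Vp in [0, 1].

    By default Vp = Vg + Ve on the single-plot basis. ``mean_basis=True``
    instead divides Ve by the mean replicate count (the repeatability of a
    genotype mean), a stricter but less common convention here.
    """
    ve = vc.Ve
    if mean_basis:
        ve = vc.Ve / (vc.n_obs / vc.n_genotypes)
    vp = vc.Vg + ve
    if vp <= 0:
        raise ValueError("Vp must be positive")
    return vc.Vg / vp


def _reml_profile(ns: np.ndarray, means: np.ndarray, ssw: float, n_total: int):
    """Concentrated REML criterion over the variance ratio gamma = Vg/Ve."""

    def neg2_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        w = ns / (1.0 + gamma * ns)
        mu = float(np.sum(w * means) / np.sum(w))
        q = ssw + float(np.sum(w * (means - mu) ** 2))
        sigma2 = q / (n_total - 1)
        return (
            (n_total - 1) * np.log(sigma2)
            + float(np.sum(np.log1p(gamma * ns)))
            + np.log(float(np.sum(w)))
        )

    return neg2_reml


def fit_random_genotype(
    records: list[PlotRecord] | None = None,
    *,
    genotype_ids: np.ndarray | None = None,
    yields: np.ndarray | None = None,
) -> tuple[VarianceComponents, list[GenotypePrediction]]:
    """Fit the random-genotype model to one environment's adjusted yields.

    Accepts either curated :class:`PlotRecord` lists (filler records are
    ignored) or raw ``genotype_ids``/``yields`` arrays. Requires at least two
    genotypes and at least one genotype with two or more observations, else
    Vg and Ve are not separately identifiable.
    """
    if records is not None:
        study = [r for r in records if not r.is_filler]
        genotype_ids = np.array([r.genotype_id for r in study])
        yields = np.array([r.dry_yield for r in study], dtype=float)
    if genotype_ids is None or yields is None:
        raise ValueError("provide records or genotype_ids and yields")
    if np.any(~np.isfinite(yields)):
        raise ValueError("yields must be finite")

    ids, inv = np.unique(genotype_ids, return_inverse=True)
    g = ids.size
    n_total = yields.size
    if g < 2:
        raise ValueError("need at least 2 genotypes")
    ns = np.bincount(inv).astype(float)
    if np.max(ns) < 2:
        raise ValueError(
            "unidentifiable design: no genotype has replicate observations"
        )
    sums = np.bincount(inv, weights=yields)
    means = sums / ns
    ssw = float(np.sum(yields**2) - np.sum(ns * means**2))

    neg2 = _reml_profile(ns, means, ssw, n_total)
    # Bounded search on log(gamma); the bounds span ratios 1e-8 .. 1e8,
    # far beyond any plausible heritability.
    res = minimize_scalar(
        neg2, bounds=(np.log(1e-8), np.log(1e8)), method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = float(np.exp(res.x))
    # Compare against the boundary gamma = 0 (Vg = 0): REML at the interior
    # optimum must not be worse, else the boundary is the estimate.
    w0 = ns.copy()
    mu0 = float(np.sum(w0 * means) / np.sum(w0))
    q0 = ssw + float(np.sum(w0 * (means - mu0) ** 2))
    neg2_at_0 = (
        (n_total - 1) * np.log(q0 / (n_total - 1)) + np.log(float(np.sum(ns)))
    )
    if neg2_at_0 <= neg2(res.x) or gamma <= 1e-8 * (1 + 1e-6):
        gamma = 0.0

    w = ns / (1.0 + gamma * ns)
    mu = float(np.sum(w * means) / np.sum(w))
    q = ssw + float(np.sum(w * (means - mu) ** 2))
    ve = q / (n_total - 1)
    vg = gamma * ve
    vc = VarianceComponents(
        Vg=vg, Ve=ve, mu=mu, n_obs=n_total, n_genotypes=g, converged=bool(res.success)
    )

    if vg + ve > 0 and vg > 0:
        shrink = vg / (vg + ve / ns)
    else:
        shrink = np.zeros(g)
    effects = shrink * (means - mu)
    preds = [
        GenotypePrediction(
            genotype_id=str(gid),
            blup_effect=float(eff),
            predicted_value=float(mu + eff),
            n_obs=int(n),
        )
        for gid, eff, n in zip(ids, effects, ns)
    ]
    return vc, preds


def build_blup_table(
    per_environment: dict[Environment, list[GenotypePrediction]],
) -> BlupTable:
    """Assemble per-environment predictions into a genotype × environment matrix.

    Genotypes absent from an environment get NaN cells. Environments are
    ordered CV before UC, years ascending within treatment; genotypes sorted
    lexically. A genotype predicted twice within one environment is an error.
    """
    if not per_environment:
        raise ValueError("no environments fitted")
    envs = sorted(per_environment, key=lambda e: (e.treatment.value, e.year))
    genotypes = sorted({p.genotype_id for preds in per_environment.values() for p in preds})
    gi = {gid: i for i, gid in enumerate(genotypes)}
    values = np.full((len(genotypes), len(envs)), np.nan)
    for j, env in enumerate(envs):
        seen: set[str] = set()
        for p in per_environment[env]:
            if p.genotype_id in seen:
                raise ValueError(f"duplicate genotype {p.genotype_id} in {env.label}")
            seen.add(p.genotype_id)
            values[gi[p.genotype_id], j] = p.predicted_value
    return BlupTable(genotypes=genotypes, environments=list(envs), values=values)


def fit_environments(
    records: list[PlotRecord],
) -> tuple[pd.DataFrame, BlupTable]:
    """Fit every year × treatment environment present in the records.

    Returns a variance-component summary frame (one row per environment,
    columns year/treatment/Vg/Ve/Vp/mu/R) and the assembled BLUP table.
    """
    groups: dict[Environment, list[PlotRecord]] = {}
    for r in records:
        if not r.is_filler:
            groups.setdefault(Environment(r.treatment, r.year), []).append(r)

    rows = []
    preds: dict[Environment, list[GenotypePrediction]] = {}
    for env in sorted(groups, key=lambda e: (e.treatment.value, e.year)):
        vc, p = fit_random_genotype(groups[env])
        preds[env] = p
        rows.append(
            {
                "year": env.year,
                "treatment": env.treatment.value,
                "Vg": vc.Vg,
                "Ve": vc.Ve,
                "Vp": vc.Vp,
                "mu": vc.mu,
                "R": vc.R,
                "n_obs": vc.n_obs,
                "n_genotypes": vc.n_genotypes,
            }
        )
    return pd.DataFrame(rows), build_blup_table(preds)
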