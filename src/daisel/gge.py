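"""GGE biplot computations: environment-centred SVD and the analytical views.

Centring each environment column by its mean removes the environment main
effect, leaving genotype main effect plus genotype-by-environment
interaction ("G + GE"); the SVD of this centred matrix underlies every GGE
view. With centred matrix C = U S V', scores are scaled by a singular-value
partitioning (SVP):

* ``genotype_focused``    — genotype scores U*S, environment scores V
* ``environment_focused`` — genotype scores U, environment scores V*S
* ``symmetric``           — both sides get sqrt(S)

Whichever SVP is used, the genotype-by-environment inner products of the
full score matrices reproduce C exactly. All views work in the first two
axes, reporting the fraction of G+GE variation the pair explains.

Views
-----
which_won_where
    Convex hull of genotype points; rays from the origin perpendicular to
    hull edges cut the plane into sectors; each environment falls in one
    sector and that sector's hull vertex is its winner (equivalently, the
    genotype maximising the score inner product with the environment).
mean_vs_stability
    The average-environment-coordination (AEC) axis points at the mean of
    environment score points; a genotype's projection on it estimates mean
    performance, its perpendicular distance instability.
ideal_genotype_ranking
    Distance to the hypothetical genotype with the largest AEC projection
    and zero instability; smaller is better.
environment_ranking
    Environment vector length (discriminating ability) and cosine of the
    angle to the AEC (representativeness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .ammi import GEMatrix

__all__ = [
    "GgeResult",
    "gge_decompose",
    "which_won_where",
    "mean_vs_stability",
    "ideal_genotype_ranking",
    "environment_ranking",
]

_SVP = ("genotype_focused", "environment_focused", "symmetric")


@dataclass
class GgeResult:
    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray  # (g, e) environment-centred matrix
    singular_values: np.ndarray  # all of them
    genotype_scores: np.ndarray  # (g, n_axes) under the chosen SVP
    environment_scores: np.ndarray  # (e, n_axes)
    svp: str
    variance_fraction: np.ndarray  # per-axis % of total G+GE variation

    @property
    def pc12_variance(self) -> float:
        """Percent of G+GE variation explained by PC1 + PC2."""
        return float(self.variance_fraction[:2].sum())

    def scores_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """First two axes of the scores; a rank-1 solution is padded with a
        zero second axis so the 2-D views stay defined."""
        gsc, esc = self.genotype_scores, self.environment_scores
        if gsc.shape[1] == 1:
            gsc = np.column_stack([gsc, np.zeros(len(gsc))])
            esc = np.column_stack([esc, np.zeros(len(esc))])
        return gsc[:, :2], esc[:, :2]


def gge_decompose(m: GEMatrix, svp: str = "symmetric") -> GgeResult:
    """Environment-centred SVD of a complete genotype × environment matrix."""
    if svp not in _SVP:
        raise ValueError(f"svp must be one of {_SVP}")
    y = m.values
    centered = y - y.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    if not keep.any():
        raise ValueError("centred matrix is zero: identical environment columns")
    u, s, v = u[:, keep], s[keep], vt[keep].T
    for k in range(s.size):  # deterministic signs, as in the AMMI axes
        if v[np.argmax(np.abs(v[:, k])), k] < 0:
            u[:, k] *= -1
            v[:, k] *= -1
    if svp == "genotype_focused":
        gsc, esc = u * s, v
    elif svp == "environment_focused":
        gsc, esc = u, v * s
    else:
        gsc, esc = u * np.sqrt(s), v * np.sqrt(s)
    frac = 100.0 * s**2 / float(np.sum(s**2))
    return GgeResult(
        genotypes=list(m.genotypes),
        environments=list(m.environments),
        centered=centered,
        singular_values=s,
        genotype_scores=gsc,
        environment_scores=esc,
        svp=svp,
        variance_fraction=frac,
    )


def _sector_of(angle: float, boundaries: np.ndarray) -> int:
    """Index of the sector [boundary_i, boundary_{i+1}) containing angle.

    Boundaries are sorted ray angles in (-pi, pi]; a point exactly on a
    boundary joins the counter-clockwise (following) sector.
    """
    idx = np.searchsorted(boundaries, angle, side="right") - 1
    return int(idx % len(boundaries))


def which_won_where(res: GgeResult) -> dict:
    """Convex-hull / sector construction identifying the winner per environment.

    Returns hull vertex indices and labels, sector boundary ray angles, the
    sector of each environment, and each environment's winning genotype.
    The winner is also computable as the genotype maximising the inner
    product of scores with the environment vector; the two constructions
    agree except exactly on sector boundaries, where ties go
    counter-clockwise.
    """
    gsc, esc = res.scores_2d()
    if len(res.genotypes) < 3:
        raise ValueError("need at least 3 genotypes")
    try:
        hull = ConvexHull(gsc)
    except Exception as exc:  # scipy QhullError on degenerate input
        raise ValueError("genotype scores are collinear; no 2-D hull") from exc
    verts = hull.vertices  # counter-clockwise order
    nv = len(verts)
    # Boundary ray for the edge (v_k, v_{k+1}): along these directions both
    # endpoints attain the same inner product, so the winner changes there.
    # The ray is the outward normal of the edge ((dy, -dx) for a CCW hull),
    # which is also the direction of the perpendicular dropped from the
    # origin onto the edge line.
    boundary_angles = np.empty(nv)
    for k in range(nv):
        a, b = gsc[verts[k]], gsc[verts[(k + 1) % nv]]
        d = b - a
        boundary_angles[k] = np.arctan2(-d[0], d[1])
    order = np.argsort(boundary_angles)
    boundaries = boundary_angles[order]
    # sector following boundary k (CCW) is won by the shared vertex of edges
    # k and k+1, i.e. vertex v_{k+1} of the edge that starts the sector
    sector_vertex = [verts[(int(order[k]) + 1) % nv] for k in range(nv)]

    env_sector = []
    winners = []
    for j in range(len(res.environments)):
        ang = float(np.arctan2(esc[j, 1], esc[j, 0]))
        sec = _sector_of(ang, boundaries)
        env_sector.append(sec)
        winners.append(res.genotypes[sector_vertex[sec]])
    return {
        "hull_vertices": [res.genotypes[i] for i in verts],
        "hull_points": gsc[verts],
        "sector_boundaries": boundaries,
        "sector_winner": [res.genotypes[i] for i in sector_vertex],
        "environment_sector": env_sector,
        "winner_per_environment": dict(zip(res.environments, winners)),
    }


def _aec_direction(res: GgeResult) -> np.ndarray:
    _, esc = res.scores_2d()
    avg = esc.mean(axis=0)
    norm = np.linalg.norm(avg)
    if norm == 0:
        raise ValueError("average environment vector has zero length")
    return avg / norm


def mean_vs_stability(res: GgeResult) -> pd.DataFrame:
    """Per-genotype AEC projection (mean performance) and signed
    perpendicular distance from the AEC axis (instability)."""
    gsc, _ = res.scores_2d()
    aec = _aec_direction(res)
    perp = np.array([-aec[1], aec[0]])
    return pd.DataFrame(
        {
            "genotype_id": res.genotypes,
            "mean_projection": gsc @ aec,
            "stability": gsc @ perp,
        }
    )


def ideal_genotype_ranking(res: GgeResult) -> pd.DataFrame:
    """Rank genotypes by distance to the ideal point on the AEC axis."""
    ms = mean_vs_stability(res)
    ideal = float(ms["mean_projection"].max())
    dist = np.hypot(ms["mean_projection"] - ideal, ms["stability"])
    out = ms.assign(distance_to_ideal=dist).sort_values("distance_to_ideal")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def environment_ranking(res: GgeResult) -> pd.DataFrame:
    """Discriminating ability (vector length) and representativeness
    (cosine of the angle to the AEC) per environment."""
    _, esc = res.scores_2d()
    aec = _aec_direction(res)
    lengths = np.linalg.norm(esc, axis=1)
    if np.any(lengths == 0):
        raise ValueError("an environment has a zero score vector")
    cosines = (esc @ aec) / lengths
    out = pd.DataFrame(
        {
            "environment": res.environments,
            "vector_length": lengths,
            "representativeness": cosines,
        }
    ).sort_values(["representativeness", "vector_length"], ascending=False)
    return out.reset_index(drop=True)
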