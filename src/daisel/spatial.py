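"""Thin-plate-spline (TPS) smoothing of field spatial trend.

Single-plant yields carry smooth field trends (soil gradients, shelter edge
effects) on top of genotype effects. A 2-D thin plate spline over the (row,
column) grid captures that trend; its residuals, re-centred on the grand
mean, give spatially adjusted yields that preserve the dataset mean exactly.

The smoother minimises the penalized least-squares criterion

    sum_i (y_i - f(x_i))^2 + lambda * J(f)

over functions f(x) = a0 + a1*row + a2*col + sum_i c_i * eta(|x - x_i|),
with the thin-plate radial basis eta(r) = r^2 log r and J the bending
energy. lambda = 0 interpolates distinct points; lambda -> infinity shrinks
to the best affine surface (the penalty's null space). When lambda is not
supplied it is chosen by generalized cross-validation (GCV) on a 40-point
log-spaced grid, ties broken toward the smoother (larger) value.

Implementation: with P the n×3 affine design and K the kernel matrix, the
stationarity system is (K + lambda*I) c + P d = y, P' c = 0. Projecting onto
an orthonormal basis Q2 of the null space of P' reduces it to the
(n-3)-dimensional symmetric system (M + lambda*I) gamma = Q2' y with
M = Q2' K Q2; one eigendecomposition of M then serves every lambda on the
GCV grid, with effective degrees of freedom
tr A(lambda) = n - lambda * sum_k 1/(d_k + lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TpsFit", "fit_tps", "adjust_yields", "adjust_records"]


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # eta(r) = r^2 log r, continuously extended by eta(0) = 0
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class TpsFit:
    """A fitted thin plate spline over field coordinates."""

    coords: np.ndarray  # (n, 2) knot coordinates (row, col)
    coefficients: np.ndarray  # (n,) radial-basis weights c
    affine: np.ndarray  # (3,) null-space coefficients (intercept, row, col)
    lam: float  # smoothing parameter actually used
    fitted: np.ndarray  # (n,) fitted surface at the data points
    residuals: np.ndarray  # (n,) observed - fitted
    edf: float  # effective degrees of freedom, tr A(lambda)
    gcv: float | None = None  # GCV score at lam (None if lam was fixed)

    def predict(self, coords: np.ndarray) -> np.ndarray:
        """Evaluate the fitted surface at new (row, col) points."""
        x = np.atleast_2d(np.asarray(coords, dtype=float))
        r = np.linalg.norm(x[:, None, :] - self.coords[None, :, :], axis=2)
        return (
            _tps_kernel(r) @ self.coefficients
            + self.affine[0]
            + x @ self.affine[1:]
        )


def fit_tps(
    coords: np.ndarray,
    values: np.ndarray,
    lam: float | None = None,
    gcv_grid_size: int = 40,
) -> TpsFit:
    """Fit a thin plate spline to yields observed at field coordinates.

    Parameters
    ----------
    coords : (n, 2) array
        (row, col) grid positions; at least 4 non-collinear points.
    values : (n,) array
        Observed yields (g·plant⁻¹).
    lam : float, optional
        Smoothing parameter; chosen by GCV when omitted. ``lam = 0``
        interpolates and requires distinct coordinates.
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or y.shape != (X.shape[0],):
        raise ValueError("coords must be (n, 2) and values (n,)")
    n = X.shape[0]
    P = np.column_stack([np.ones(n), X])
    if n < 4 or np.linalg.matrix_rank(P) < 3:
        raise ValueError("need at least 4 non-collinear points")

    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    K = _tps_kernel(r)

    Q, _ = np.linalg.qr(P, mode="complete")
    Q2 = Q[:, 3:]
    M = Q2.T @ K @ Q2
    M = 0.5 * (M + M.T)
    d, U = np.linalg.eigh(M)
    d = np.clip(d, 0.0, None)  # kernel is conditionally PD; clip round-off
    z = U.T @ (Q2.T @ y)

    def scores(l: float) -> tuple[float, float, float]:
        denom = d + l
        rss = float(l * l * np.sum((z / denom) ** 2)) if l > 0 else 0.0
        edf = n - (l * float(np.sum(1.0 / denom)) if l > 0 else 0.0)
        gcv = n * rss / (n - edf) ** 2 if n > edf else np.inf
        return rss, edf, gcv

    gcv_score: float | None = None
    if lam is None:
        scale = float(np.mean(d)) if np.any(d > 0) else 1.0
        grid = np.geomspace(1e-6 * scale, 1e4 * scale, gcv_grid_size)
        best_lam, best_gcv = grid[0], np.inf
        for l in grid:
            _, _, g = scores(float(l))
            if g <= best_gcv:  # <= prefers the larger (smoother) lambda on ties
                best_lam, best_gcv = float(l), g
        lam = best_lam
        gcv_score = best_gcv
    elif lam < 0:
        raise ValueError("lambda must be >= 0")

    if lam == 0 and np.any(d <= 0):
        raise ValueError("lambda = 0 requires distinct, non-degenerate points")

    gamma = U @ (z / (d + lam)) if lam > 0 else U @ (z / np.where(d > 0, d, 1.0))
    c = Q2 @ gamma
    resid = lam * c if lam > 0 else np.zeros(n)
    fitted = y - resid
    affine, *_ = np.linalg.lstsq(P, y - (K + lam * np.eye(n)) @ c, rcond=None)
    _, edf, _ = scores(float(lam))

    return TpsFit(
        coords=X,
        coefficients=c,
        affine=affine,
        lam=float(lam),
        fitted=fitted,
        residuals=resid,
        edf=float(edf),
        gcv=gcv_score,
    )


def adjust_yields(fit: TpsFit, values: np.ndarray) -> np.ndarray:
    """Spatially adjusted yields: grand mean plus TPS residuals.

    ``adjusted_i = mean(values) + residual_i``, so the grand mean of the
    adjusted data equals the grand mean of the input to machine precision
    whenever the residuals sum to zero, and the spatial trend captured by
    the spline is removed.
    """
    y = np.asarray(values, dtype=float)
    if y.shape != fit.residuals.shape:
        raise ValueError("values do not match the fitted data")
    return float(np.mean(y)) + fit.residuals


def adjust_records(records, lam=None, per_block: bool = False):
    """Adjust dry yields of plot records, one surface per year × treatment field.

    With ``per_block=True`` each block gets its own surface. Filler records
    pass through unadjusted. Returns (adjusted records, fits keyed by group).
    """
    def key(r):
        k = (r.year, r.treatment.value)
        return k + (r.block,) if per_block else k

    groups: dict[tuple, list] = {}
    for rec in records:
        if not rec.is_filler:
            groups.setdefault(key(rec), []).append(rec)

    out = [r for r in records if r.is_filler]
    fits: dict[tuple, TpsFit] = {}
    for k in sorted(groups):
        grp = groups[k]
        coords = np.array([[r.row, r.col] for r in grp], dtype=float)
        y = np.array([r.dry_yield for r in grp], dtype=float)
        fit = fit_tps(coords, y, lam=lam)
        adj = adjust_yields(fit, y)
        fits[k] = fit
        out.extend(r.with_dry_yield(max(float(a), 0.0)) for r, a in zip(grp, adj))
    return out, fits
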