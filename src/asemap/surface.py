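"""Fitted maternal-probability surfaces, cross-sections, and raw-fraction maps.

A fitted gene model induces a smooth probability surface p(x) over the
tissue. This module evaluates it on arbitrary grids with pointwise
delta-method confidence intervals constructed on the logit scale (so the
bounds respect [0, 1]), extracts 1D cross-sections along line segments,
and tabulates raw per-spot maternal fractions for plotting beside the
model surface. Grid points outside the tissue (no nearby spots) can be
masked via a Delaunay-based concave hull to avoid extrapolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay
from scipy.special import expit, logit

from .data_model import SpatialAllelicCounts
from .fitter import GeneFit
from .spline import SplineBasis, evaluate_basis

__all__ = [
    "SurfaceEstimate",
    "predict_surface",
    "cross_section",
    "raw_fraction_map",
    "tissue_mask",
]


@dataclass
class SurfaceEstimate:
    """Gridded maternal-probability surface with pointwise confidence bounds."""

    grid_coords: np.ndarray
    p_hat: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    source_fit: str
    k_used: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": self.grid_coords[:, 0],
                "x2": self.grid_coords[:, 1],
                "p_hat": self.p_hat,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _grid_jacobian(fit: GeneFit, B: np.ndarray) -> np.ndarray:
    """(K, M, P) tensor of d eta_k / d beta at the grid points."""
    K = len(fit.cell_types)
    M_pts, L = B.shape
    mask = fit.design_info.get("spline_cts")
    mask = np.ones(K, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if fit.shared_spline:
        P = K + L
    else:
        P = K + L * int(mask.sum())
    if P != fit.beta_hat.size:
        raise ValueError(
            f"basis with {L} columns does not match fit with {fit.beta_hat.size} "
            "parameters; was the fit built from this basis?"
        )
    J = np.zeros((K, M_pts, P))
    for k in range(K):
        J[k, :, k] = 1.0
    if L:
        if fit.shared_spline:
            for k in range(K):
                J[k, :, K:] = B
        else:
            j = K
            for k in range(K):
                if mask[k]:
                    J[k, :, j : j + L] = B
                    j += L
    return J


def predict_surface(
    fit: GeneFit,
    basis: SplineBasis,
    grid: np.ndarray,
    level: float = 0.95,
    cell_type: str = "overall",
    alpha_bar: np.ndarray | None = None,
) -> SurfaceEstimate:
    """Evaluate the fitted maternal-probability surface with pointwise CIs.

    For a named cell type the surface is that cell type's expit predictor;
    for ``"overall"`` the cell-type expits are averaged with weights
    ``alpha_bar`` (default: the fit's spot-averaged mixture shares when
    recorded, else uniform). Uncertainty is propagated by the delta
    method and the interval is built on the logit scale, so bounds stay
    inside [0, 1]. For a single-predictor surface this reduces exactly to
    eta +/- z * se(eta) mapped through expit.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    K = len(fit.cell_types)
    if fit.beta_hat.size > K:
        B = evaluate_basis(basis, grid)
    else:
        B = np.zeros((grid.shape[0], 0))
    J = _grid_jacobian(fit, B)
    eta = np.stack([J[k] @ fit.beta_hat for k in range(K)], axis=1)
    sig = expit(eta)

    if cell_type == "overall":
        if alpha_bar is None:
            alpha_bar = fit.design_info.get("alpha_bar")
            alpha_bar = (
                np.full(K, 1.0 / K) if alpha_bar is None else np.asarray(alpha_bar, float)
            )
        w = np.asarray(alpha_bar, dtype=float)
        if w.shape != (K,):
            raise ValueError("alpha_bar must have one weight per cell type")
        w = w / w.sum()
    else:
        idx = np.flatnonzero(fit.cell_types.astype(str) == str(cell_type))
        if idx.size == 0:
            raise KeyError(
                f"cell type {cell_type!r} not in fit ({list(fit.cell_types)})"
            )
        w = np.zeros(K)
        w[idx[0]] = 1.0

    p = sig @ w
    # delta method: dp/dbeta = sum_k w_k sigma'(eta_k) J_k
    G = np.einsum("k,mk,kmp->mp", w, sig * (1 - sig), J)
    var_p = np.einsum("mp,pq,mq->m", G, fit.cov_beta, G)
    var_p = np.clip(var_p, 0.0, None)
    if (np.diag(fit.cov_beta) < 0).any():
        var_p = np.maximum(var_p, 0.0)
    se_p = np.sqrt(var_p)
    z = stats.norm.ppf(0.5 + level / 2)
    eps = 1e-12
    pc = np.clip(p, eps, 1 - eps)
    se_logit = se_p / (pc * (1 - pc))
    lo = expit(logit(pc) - z * se_logit)
    hi = expit(logit(pc) + z * se_logit)
    return SurfaceEstimate(
        grid_coords=grid,
        p_hat=p,
        ci_lower=np.minimum(lo, p),
        ci_upper=np.maximum(hi, p),
        level=level,
        source_fit=fit.gene_id,
        k_used=fit.design_info.get("k"),
    )


def cross_section(
    fit: GeneFit,
    basis: SplineBasis,
    point: np.ndarray,
    direction: np.ndarray,
    length: float,
    n_points: int = 100,
    level: float = 0.95,
    cell_type: str = "overall",
) -> pd.DataFrame:
    """Surface estimate along a line segment, arc-length parameterized.

    The segment starts at ``point`` and proceeds ``length`` units along
    ``direction`` (e.g. a vertical line "starting at the arrow and moving
    up"). Values agree exactly with :func:`predict_surface` at the same
    coordinates.
    """
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if length <= 0 or norm == 0:
        raise ValueError("cross-section segment must have positive length")
    unit = direction / norm
    t = np.linspace(0.0, length, n_points)
    pts = point[None, :] + t[:, None] * unit[None, :]
    est = predict_surface(fit, basis, pts, level=level, cell_type=cell_type)
    df = est.to_frame()
    df.insert(0, "arc_length", t)
    return df


def raw_fraction_map(counts: SpatialAllelicCounts, gene_id: str) -> pd.DataFrame:
    """Per-spot raw maternal fractions (spots with N > 0 only).

    Columns: spot_id, x1, x2, fraction, total — fraction colors a spot
    map (red maternal, blue paternal), total sizes the dots.
    """
    y, n = counts.gene_vectors(gene_id)
    keep = n > 0
    return pd.DataFrame(
        {
            "spot_id": counts.spot_ids[keep],
            "x1": counts.coords[keep, 0],
            "x2": counts.coords[keep, 1],
            "fraction": y[keep] / n[keep],
            "total": n[keep].astype(int),
        }
    )


def tissue_mask(
    grid: np.ndarray, coords: np.ndarray, radius: float | None = None
) -> np.ndarray:
    """True for grid points inside the concave hull of the observed spots.

    Delaunay triangles of the spot cloud whose circumradius exceeds
    ``radius`` (default: 4x the median nearest-neighbor spacing) are
    discarded; grid points are kept if they fall in a remaining triangle.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    coords = np.asarray(coords, dtype=float)
    tri = Delaunay(coords)
    if radius is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(coords).query(coords, k=2)
        radius = 4.0 * float(np.median(d[:, 1]))
    pa, pb, pc = (coords[tri.simplices[:, i]] for i in range(3))
    a = np.linalg.norm(pb - pc, axis=1)
    b = np.linalg.norm(pa - pc, axis=1)
    c = np.linalg.norm(pa - pb, axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 1e-300, None))
    circum = a * b * c / (4.0 * area)
    good = circum <= radius
    simplex = tri.find_simplex(grid)
    inside = simplex >= 0
    inside[inside] = good[simplex[inside]]
    return inside
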