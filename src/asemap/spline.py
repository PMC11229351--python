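"""Low-rank 2D thin-plate regression spline bases.

A smooth spatial effect is represented with ``k`` degrees of freedom: the
radial kernel eta(r) = r^2 log r evaluated on pairwise spot distances is
eigendecomposed and truncated to its leading directions, the linear
null-space terms (x1, x2) are retained, and the constant direction is
absorbed by centering each column over the training spots (the regression
model supplies its own intercept). The emitted design therefore has
L = k - 1 columns whose span contains linear functions of the coordinates.

Out-of-sample evaluation uses the Nystrom extension of the eigenvectors,
so evaluating at the training coordinates reproduces the stored design.
Coordinates are standardized (centered, scaled by root-mean-square
distance) before kernel evaluation for numerical conditioning; the
constants are stored and applied transparently at evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SplineBasis", "build_tps_basis", "evaluate_basis"]


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _digest(coords: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(coords, dtype=np.float64).tobytes()).hexdigest()[:16]


@dataclass
class SplineBasis:
    """A fitted thin-plate regression spline basis.

    Attributes
    ----------
    k : int
        Requested degrees of freedom; the emitted design has L = k - 1
        columns (constant absorbed).
    center, scale : standardization constants for the coordinates.
    knots : ndarray, S x 2
        Standardized training coordinates (kernel centers).
    nystrom_coef : ndarray, S x (k - 3)
        Eigenvector / eigenvalue coefficients for out-of-sample extension.
    col_means : ndarray, L
        Training-column means absorbed by the sum-to-zero constraint.
    col_scales : ndarray, L
        Root-mean-square of each centered column; columns are divided by
        these so all basis functions carry unit scale.
    design : ndarray, S x L
        Centered, scaled design columns at the training coordinates.
    """

    k: int
    center: np.ndarray
    scale: float
    knots: np.ndarray
    nystrom_coef: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    design: np.ndarray
    training_coords_digest: str

    @property
    def L(self) -> int:
        return self.k - 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "center": self.center.tolist(),
            "scale": self.scale,
            "knots": self.knots.tolist(),
            "nystrom_coef": self.nystrom_coef.tolist(),
            "col_means": self.col_means.tolist(),
            "col_scales": self.col_scales.tolist(),
            "design": self.design.tolist(),
            "training_coords_digest": self.training_coords_digest,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplineBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            center=np.array(d["center"]),
            scale=d["scale"],
            knots=np.array(d["knots"]),
            nystrom_coef=np.array(d["nystrom_coef"]),
            col_means=np.array(d["col_means"]),
            col_scales=np.array(d["col_scales"]),
            design=np.array(d["design"]),
            training_coords_digest=d["training_coords_digest"],
        )


def build_tps_basis(coords: np.ndarray, k: int = 5) -> SplineBasis:
    """Construct a thin-plate regression spline basis of dimension ``k``.

    Parameters
    ----------
    coords : ndarray, S x 2
        Spot coordinates.
    k : int
        Degrees of freedom; k=5 is the default for hypothesis testing,
        k=15 resolves finer structure for visualization surfaces.

    Raises
    ------
    ValueError
        If S <= k (lower k) or the coordinate geometry is degenerate
        (coincident or collinear spots).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be S x 2")
    S = coords.shape[0]
    if k < 3:
        raise ValueError("k must be at least 3 (two linear terms + one smooth)")
    if S < k:
        raise ValueError(f"need at least k={k} spots (got {S}); lower k")

    center = coords.mean(axis=0)
    centered = coords - center
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    if scale <= 0:
        raise ValueError("degenerate coordinates: all spots coincide")
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] / sv[0] < 1e-10:
        raise ValueError("degenerate coordinates: spots are collinear")
    Z = centered / scale

    m = k - 3  # number of kernel eigen-directions
    if m > 0:
        E = _tps_kernel(cdist(Z, Z))
        eigval, eigvec = np.linalg.eigh(E)
        order = np.argsort(-np.abs(eigval))[:m]
        lam = eigval[order]
        U = eigvec[:, order]
        # deterministic sign: largest-magnitude component of each vector positive
        for j in range(m):
            i = int(np.argmax(np.abs(U[:, j])))
            if U[i, j] < 0:
                U[:, j] = -U[:, j]
        nystrom = U / lam  # E @ nystrom == U at training points
        cols = np.column_stack([Z, U])
    else:
        nystrom = np.zeros((S, 0))
        cols = Z.copy()

    col_means = cols.mean(axis=0)
    design = cols - col_means
    # unit-RMS columns: same span, better conditioning, coefficients on a
    # common scale across the linear and kernel directions
    col_scales = np.sqrt((design**2).mean(axis=0))
    col_scales[col_scales == 0] = 1.0
    design = design / col_scales
    return SplineBasis(
        k=k,
        center=center,
        scale=scale,
        knots=Z,
        nystrom_coef=nystrom,
        col_means=col_means,
        col_scales=col_scales,
        design=design,
        training_coords_digest=_digest(coords),
    )


def evaluate_basis(basis: SplineBasis, new_coords: np.ndarray) -> np.ndarray:
    """Evaluate the basis functions at arbitrary coordinates.

    Returns an M x L matrix; at the training coordinates this reproduces
    the stored design columns.
    """
    new_coords = np.atleast_2d(np.asarray(new_coords, dtype=float))
    if new_coords.shape[1] != 2:
        raise ValueError("new_coords must be M x 2")
    Z = (new_coords - basis.center) / basis.scale
    if basis.nystrom_coef.shape[1] > 0:
        Enew = _tps_kernel(cdist(Z, basis.knots))
        cols = np.column_stack([Z, Enew @ basis.nystrom_coef])
    else:
        cols = Z
    return (cols - basis.col_means) / basis.col_scales
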