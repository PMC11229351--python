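"""Per-gene maximum-likelihood estimation by trust-region Newton.

Each gene is fitted independently: starting from beta = 0 (every cell type
at p = 0.5) with a method-of-moments overdispersion warm start, the
quadratic model of the log-likelihood is maximized within an adaptively
sized trust region (accept when the achieved/predicted improvement ratio
exceeds 0.1; shrink the radius x0.5 below 0.25, grow x2 above 0.75), then
phi is re-estimated by bounded scalar maximization, alternating to joint
convergence. The Wald covariance is the inverse observed information in
beta at the optimum, with phi treated as fixed; non-positive-definite
information matrices are ridged (recorded in the fit's warnings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.linalg import cho_factor, cho_solve

from .betabinom import (
    PHI_BOUNDS,
    GeneDesign,
    estimate_phi,
    loglik,
    loglik_grad_hess,
    mixture_mean,
    phi_moment_estimate,
)
from .data_model import CellTypeWeights, ExpressionRates, SpatialAllelicCounts
from .mixture import compute_alpha, default_rates
from .spline import SplineBasis

__all__ = ["FitOptions", "GeneFit", "make_design", "fit_gene", "fit_all", "fits_to_frame"]


@dataclass
class FitOptions:
    """Tunable optimizer constants (trust-region strategy is fixed; these
    are the engineering defaults)."""

    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_grad: float = 1e-6
    delta0: float = 1.0
    delta_max: float = 1e3
    accept_ratio: float = 0.1
    shrink_threshold: float = 0.25
    grow_threshold: float = 0.75
    max_alternations: int = 50
    fixed_phi: float | None = None
    phi_bounds: tuple[float, float] = PHI_BOUNDS


@dataclass
class GeneFit:
    """Result of one gene's maximum-likelihood fit."""

    gene_id: str
    beta_hat: np.ndarray
    phi_hat: float
    loglik: float
    cov_beta: np.ndarray
    converged: bool
    n_iterations: int
    param_names: list[str]
    cell_types: np.ndarray
    shared_spline: bool
    design_info: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0, None))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_id": self.gene_id,
            "beta_hat": self.beta_hat.tolist(),
            "phi_hat": self.phi_hat,
            "loglik": self.loglik,
            "cov_beta": self.cov_beta.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "param_names": self.param_names,
            "cell_types": [str(c) for c in self.cell_types],
            "shared_spline": self.shared_spline,
            "design_info": self.design_info,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Design construction


def make_design(
    counts: SpatialAllelicCounts,
    gene_id: str,
    weights: CellTypeWeights | None = None,
    rates: ExpressionRates | None = None,
    covariates: SplineBasis | np.ndarray | None = None,
    shared_spline: bool = True,
    spline_cts: Sequence[bool] | None = None,
    ct_share_floor: float = 1.0,
) -> GeneDesign:
    """Assemble the usable-spot design for one gene.

    Usable spots have n > 0 and a well-defined mixture row. Cell types
    whose total share over expressing spots falls below ``ct_share_floor``
    are dropped for identifiability (their residual share is renormalized
    away); the drop is recorded in ``design_info``.
    """
    gene_id = str(gene_id)
    y, n = counts.gene_vectors(gene_id)
    S = counts.n_spots

    if weights is None:
        A = np.ones((S, 1))
        valid = np.ones(S, dtype=bool)
        cell_types = np.array(["all"], dtype=object)
    else:
        w = weights.align_spots(counts.spot_ids)
        if rates is None:
            rates = default_rates([gene_id], w.cell_types)
        alpha = compute_alpha(w, rates, gene_id)
        A, valid, cell_types = alpha.A, alpha.valid_mask, alpha.cell_types

    usable = (n > 0) & valid
    ct_mask = None if spline_cts is None else np.asarray(spline_cts, dtype=bool)
    dropped_cts: list[str] = []
    if A.shape[1] > 1:
        share = A[usable].sum(axis=0)
        keep = share >= ct_share_floor
        if not keep.any():
            keep = share == share.max()
        if not keep.all():
            dropped_cts = [str(c) for c in cell_types[~keep]]
            A = A[:, keep]
            cell_types = cell_types[keep]
            if ct_mask is not None:
                ct_mask = ct_mask[keep]
            rowsum = A.sum(axis=1)
            valid = valid & (rowsum > 0)
            A = np.divide(A, rowsum[:, None], out=np.zeros_like(A), where=rowsum[:, None] > 0)
            usable = (n > 0) & valid

    if not usable.any():
        raise ValueError(f"gene {gene_id!r} has no usable spots")

    if covariates is None:
        X = np.zeros((int(usable.sum()), 0))
        k = None
    elif isinstance(covariates, SplineBasis):
        X = covariates.design[usable]
        k = covariates.k
    else:
        X = np.asarray(covariates, dtype=float)[usable]
        k = None

    design = GeneDesign(
        gene_id=gene_id,
        y=y[usable],
        n=n[usable],
        A=A[usable],
        X=X,
        cell_types=cell_types,
        shared_spline=shared_spline,
        spline_cts=ct_mask,
        usable_index=np.flatnonzero(usable),
    )
    design.info = {
        "dropped_cell_types": dropped_cts,
        "k": k,
        "spline_cts": None if ct_mask is None else ct_mask.tolist(),
        "alpha_bar": A[usable].mean(axis=0).tolist(),
    }
    return design


# ---------------------------------------------------------------------------
# Trust-region subproblem and Newton loop


def _solve_subproblem(g: np.ndarray, H: np.ndarray, delta: float):
    """Maximize g's + s'Hs/2 subject to ||s|| <= delta.

    Eigendecomposition of B = -H plus bisection on the Levenberg shift
    for the boundary case; returns the step and its predicted gain.
    """
    B = -H
    lam, Q = np.linalg.eigh(B)
    gq = Q.T @ g

    def step(shift: float) -> np.ndarray:
        return Q @ (gq / (lam + shift))

    lam_min = lam.min()
    if lam_min > 0:
        s = step(0.0)
        if np.linalg.norm(s) <= delta:
            return s, float(g @ s + 0.5 * s @ H @ s)
    lo = max(0.0, -lam_min) + 1e-12
    s = step(lo)
    if np.linalg.norm(s) > delta:
        hi = lo + 1.0
        while np.linalg.norm(step(hi)) > delta:
            hi *= 2.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(step(mid)) > delta:
                lo = mid
            else:
                hi = mid
        s = step(hi)
    pred = float(g @ s + 0.5 * s @ H @ s)
    return s, pred


def _tr_maximize(
    beta: np.ndarray, phi: float, design: GeneDesign, opt: FitOptions
) -> tuple[np.ndarray, float, int, list[str]]:
    warnings: list[str] = []
    ll, g, H = loglik_grad_hess(beta, phi, design)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood at initialization")
    delta = opt.delta0
    n_iter = 0
    for n_iter in range(1, opt.max_iter + 1):
        if np.linalg.norm(g) < opt.tol_grad:
            break
        s, pred = _solve_subproblem(g, H, delta)
        if pred <= 0:
            delta *= 0.5
            if delta < 1e-14:
                break
            continue
        ll_new = loglik(beta + s, phi, design)
        ratio = (ll_new - ll) / pred if np.isfinite(ll_new) else -np.inf
        accepted = ratio > opt.accept_ratio
        if accepted:
            if ll_new < ll:  # contract: accepted steps never decrease the objective
                warnings.append("accepted step decreased log-likelihood")
                break
            gain = ll_new - ll
            beta = beta + s
            ll, g, H = loglik_grad_hess(beta, phi, design)
            if ratio > opt.grow_threshold and np.linalg.norm(s) >= 0.99 * delta:
                delta = min(2.0 * delta, opt.delta_max)
            if gain < opt.tol_loglik:
                break
        if ratio < opt.shrink_threshold:
            delta *= 0.5
            if delta < 1e-14:
                break
    return beta, ll, n_iter, warnings


def _covariance(beta: np.ndarray, phi: float, design: GeneDesign):
    _, _, H = loglik_grad_hess(beta, phi, design)
    B = -H
    ridge = 0.0
    eye = np.eye(B.shape[0])
    for m in range(0, 60):
        trial = B + ridge * eye
        try:
            c = cho_factor(trial)
            cov = cho_solve(c, eye)
            return 0.5 * (cov + cov.T), ridge
        except np.linalg.LinAlgError:
            ridge = 1e-8 * 2**m
    raise np.linalg.LinAlgError("information matrix could not be regularized")


def fit_gene(design: GeneDesign, options: FitOptions | None = None) -> GeneFit:
    """Fit one gene by alternating trust-region beta-steps and phi-steps."""
    opt = options or FitOptions()
    if design.S < 1:
        raise ValueError("no usable spots")
    if design.n_params > design.S:
        raise ValueError(
            f"{design.n_params} parameters for {design.S} usable spots; "
            "reduce k or use shared spline coefficients"
        )
    warnings: list[str] = []
    beta = np.zeros(design.n_params)
    if opt.fixed_phi is not None:
        phi = float(opt.fixed_phi)
    else:
        phi = phi_moment_estimate(design.y, design.n)

    total_iter = 0
    ll_joint = -np.inf
    converged = False
    for _ in range(opt.max_alternations):
        beta, ll, n_iter, w = _tr_maximize(beta, phi, design, opt)
        warnings.extend(w)
        total_iter += n_iter
        if opt.fixed_phi is None:
            est = estimate_phi(beta, design, opt.phi_bounds)
            phi, ll = est.phi, est.log_likelihood_at_phi
            if est.flat:
                warnings.append("phi unidentifiable: all usable spots have n = 1")
            elif est.at_boundary:
                warnings.append(f"phi at boundary ({phi:.2e})")
        if abs(ll - ll_joint) < opt.tol_loglik:
            converged = True
            ll_joint = ll
            break
        ll_joint = ll
        if opt.fixed_phi is not None:
            # single beta-problem: convergence decided by the inner loop
            _, g, _ = loglik_grad_hess(beta, phi, design)
            converged = bool(np.linalg.norm(g) < opt.tol_grad or n_iter < opt.max_iter)
            break

    if np.abs(design.eta(beta)).max() >= 15.0 - 1e-9:
        warnings.append("linear predictor clipped: possible complete separation")
    cov, ridge = _covariance(beta, phi, design)
    if ridge > 0:
        warnings.append(f"covariance ridge {ridge:.2e}")
    info = dict(getattr(design, "info", {}))
    info.update(shared_spline=design.shared_spline, n_usable_spots=design.S)
    return GeneFit(
        gene_id=design.gene_id,
        beta_hat=beta,
        phi_hat=phi,
        loglik=ll_joint,
        cov_beta=cov,
        converged=converged,
        n_iterations=total_iter,
        param_names=design.param_names(),
        cell_types=design.cell_types,
        shared_spline=design.shared_spline,
        design_info=info,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Parallel driver


def _fit_one(counts, gene_id, weights, rates, covariates, shared_spline, options):
    try:
        design = make_design(
            counts, gene_id, weights=weights, rates=rates,
            covariates=covariates, shared_spline=shared_spline,
        )
        return gene_id, fit_gene(design, options)
    except Exception as e:  # per-gene failures are captured, not fatal
        return gene_id, e


def fit_all(
    counts: SpatialAllelicCounts,
    gene_ids: Sequence[str] | None = None,
    weights: CellTypeWeights | None = None,
    rates: ExpressionRates | None = None,
    covariates: SplineBasis | np.ndarray | None = None,
    shared_spline: bool = True,
    options: FitOptions | None = None,
    n_jobs: int = 1,
) -> dict[str, GeneFit | Exception]:
    """Fit many genes independently; results do not depend on worker count.

    Returns a dict keyed by gene id in input order; entries are GeneFit
    objects, or the captured exception for genes whose fit failed.
    """
    if gene_ids is None:
        gene_ids = [str(g) for g in counts.gene_ids]
    gene_ids = [str(g) for g in gene_ids]
    if not gene_ids:
        import warnings as _w

        _w.warn("fit_all called with an empty gene list")
        return {}
    results = Parallel(n_jobs=n_jobs)(
        delayed(_fit_one)(counts, g, weights, rates, covariates, shared_spline, options)
        for g in gene_ids
    )
    return {g: r for g, r in results}


def fits_to_frame(fits: dict[str, GeneFit | Exception]) -> pd.DataFrame:
    """One row per gene x coefficient, for TSV export."""
    rows = []
    for g, fit in fits.items():
        if isinstance(fit, Exception):
            rows.append({"gene": g, "error": str(fit)})
            continue
        for name, b, se in zip(fit.param_names, fit.beta_hat, fit.se):
            rows.append(
                {
                    "gene": g,
                    "parameter": name,
                    "estimate": b,
                    "se": se,
                    "phi": fit.phi_hat,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "n_iterations": fit.n_iterations,
                    "warnings": "; ".join(fit.warnings),
                }
            )
    return pd.DataFrame(rows)
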