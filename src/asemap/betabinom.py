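"""Beta-binomial kernel, mixture-of-expit mean, and gene log-likelihood.

Maternal counts y at a spot with n allele-resolved transcripts follow

    y ~ BetaBinomial(p, n, phi),

parameterized by the mean maternal probability p and a gene-level
overdispersion phi in [0, 1): the underlying Beta has a = p(1-phi)/phi and
b = (1-p)(1-phi)/phi, so phi -> 0 recovers the binomial and phi -> 1
approaches all-or-none allelic sampling ("bursting"). The mean is a
cell-type mixture of inverse-logit linear predictors,

    p_i = sum_k alpha[i,k] * expit(beta_{0,k} + sum_l beta_{l,k} * G[i,l]),

with covariates G (e.g. a thin-plate spline design) whose coefficients may
be cell-type-specific or shared across cell types. This module provides
the log pmf, the mean, and the exact analytic gradient and Hessian of the
gene log-likelihood in beta (chain rule through the mixture mean, with
digamma/trigamma terms for the derivative in p), plus bounded-scalar
maximum-likelihood estimation of phi with beta held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, gammaln, digamma, polygamma

__all__ = [
    "ETA_CLIP",
    "GeneDesign",
    "OverdispersionEstimate",
    "betabinom_logpmf",
    "mixture_mean",
    "loglik",
    "loglik_grad_hess",
    "estimate_phi",
    "phi_moment_estimate",
]

# Linear predictors are clipped to +/- ETA_CLIP inside the expit; complete
# separation (e.g. an all-maternal gene) otherwise drives eta to infinity.
ETA_CLIP = 15.0

PHI_BOUNDS = (1e-6, 1.0 - 1e-6)


def _trigamma(x):
    return polygamma(1, x)


def betabinom_logpmf(y, n, p, phi):
    """Log pmf of the beta-binomial in mean/overdispersion form.

    ``phi = 0`` evaluates the exact binomial limit; ``p`` equal to 0 or 1
    is the degenerate point mass at y = 0 or y = n. Inputs broadcast.
    """
    y = np.asarray(y)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if (y > n).any():
        raise ValueError("y > n")
    if (y < 0).any() or (n < 0).any():
        raise ValueError("negative counts")
    if (phi < 0).any() or (phi >= 1).any():
        raise ValueError("phi must lie in [0, 1)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p must lie in [0, 1]")
    y, n, p, phi = np.broadcast_arrays(y, n, p, phi)
    out = np.empty(y.shape, dtype=float)

    point = (p == 0) | (p == 1)
    if point.any():
        hit = np.where(p[point] == 0, y[point] == 0, y[point] == n[point])
        out[point] = np.where(hit, 0.0, -np.inf)

    # below ~1e-12 the beta-binomial is binomial to machine precision and
    # c = (1-phi)/phi would overflow the log-gamma path
    binom = (~point) & (phi < 1e-12)
    if binom.any():
        out[binom] = _binom_logpmf(y[binom], n[binom], p[binom])

    bb = (~point) & (phi >= 1e-12)
    if bb.any():
        yb, nb, pb, phib = y[bb], n[bb], p[bb], phi[bb]
        c = (1 - phib) / phib
        a = pb * c
        b = (1 - pb) * c
        out[bb] = (
            gammaln(nb + 1)
            - gammaln(yb + 1)
            - gammaln(nb - yb + 1)
            + gammaln(yb + a)
            + gammaln(nb - yb + b)
            - gammaln(nb + c)
            - gammaln(a)
            - gammaln(b)
            + gammaln(c)
        )
    return out if out.ndim else float(out)


def _binom_logpmf(y, n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(p), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
    lc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return lc + t1 + t2


def _bb_terms(y, n, p, phi, order=2):
    """Per-observation log pmf and its first/second derivative in p."""
    if phi == 0:
        f = _binom_logpmf(y, n, p)
        f1 = y / p - (n - y) / (1 - p)
        f2 = -y / p**2 - (n - y) / (1 - p) ** 2
        return f, f1, f2
    c = (1 - phi) / phi
    a = p * c
    b = (1 - p) * c
    f = (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + gammaln(y + a)
        + gammaln(n - y + b)
        - gammaln(n + c)
        - gammaln(a)
        - gammaln(b)
        + gammaln(c)
    )
    if order == 0:
        return f, None, None
    f1 = c * (digamma(y + a) - digamma(a) - digamma(n - y + b) + digamma(b))
    if order == 1:
        return f, f1, None
    f2 = c**2 * (
        _trigamma(y + a) - _trigamma(a) + _trigamma(n - y + b) - _trigamma(b)
    )
    return f, f1, f2


@dataclass
class GeneDesign:
    """Usable-spot data and covariate structure for one gene's likelihood.

    ``A`` holds mixture shares over the retained cell types (rows sum
    to 1), ``X`` the covariate columns (possibly zero columns for an
    intercept-only model). Parameters are laid out as K intercepts
    followed by covariate coefficients: a single block of L shared across
    cell types when ``shared_spline``, otherwise one L-block per cell
    type flagged in ``spline_cts`` (default: all of them).
    """

    gene_id: str
    y: np.ndarray
    n: np.ndarray
    A: np.ndarray
    X: np.ndarray
    cell_types: np.ndarray = field(default_factory=lambda: np.array(["all"], dtype=object))
    shared_spline: bool = True
    spline_cts: np.ndarray | None = None
    usable_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1) if self.X.size else self.X.reshape(len(self.y), 0)
        S = len(self.y)
        if self.A.shape[0] != S or len(self.n) != S or self.X.shape[0] != S:
            raise ValueError("inconsistent spot dimension in design")
        if (self.n <= 0).any():
            raise ValueError("usable spots must have n > 0")
        if (self.y < 0).any() or (self.y > self.n).any():
            raise ValueError("require 0 <= y <= n")
        rowsum = self.A.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-8:
            raise ValueError("mixture rows must sum to 1 on usable spots")
        if self.spline_cts is None:
            self.spline_cts = np.ones(self.A.shape[1], dtype=bool)
        else:
            self.spline_cts = np.asarray(self.spline_cts, dtype=bool)
            if self.spline_cts.shape != (self.A.shape[1],):
                raise ValueError("spline_cts must have one flag per cell type")

    @property
    def S(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return self.A.shape[1]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        if self.shared_spline:
            return self.K + self.L
        return self.K + self.L * int(self.spline_cts.sum())

    def eta(self, beta: np.ndarray) -> np.ndarray:
        """Linear predictors, S x K."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector length {beta.size} != {self.n_params}"
            )
        eta = np.repeat(beta[: self.K][None, :], self.S, axis=0)
        if self.L == 0:
            return eta
        if self.shared_spline:
            eta = eta + (self.X @ beta[self.K :])[:, None]
        else:
            j = self.K
            for k in range(self.K):
                if self.spline_cts[k]:
                    eta[:, k] += self.X @ beta[j : j + self.L]
                    j += self.L
        return eta

    def param_jacobian(self) -> np.ndarray:
        """d eta[:, k] / d beta as a (K, S, P) tensor (constant in beta)."""
        P, S, K, L = self.n_params, self.S, self.K, self.L
        M = np.zeros((K, S, P))
        for k in range(K):
            M[k, :, k] = 1.0
        if L:
            if self.shared_spline:
                for k in range(K):
                    M[k, :, K:] = self.X
            else:
                j = K
                for k in range(K):
                    if self.spline_cts[k]:
                        M[k, :, j : j + L] = self.X
                        j += L
        return M

    def param_names(self) -> list[str]:
        names = [f"intercept[{c}]" for c in self.cell_types]
        if self.L == 0:
            return names
        if self.shared_spline:
            names.extend(f"cov{l+1}" for l in range(self.L))
        else:
            for k, c in enumerate(self.cell_types):
                if self.spline_cts[k]:
                    names.extend(f"cov{l+1}[{c}]" for l in range(self.L))
        return names


@dataclass
class OverdispersionEstimate:
    """Maximum-likelihood overdispersion with beta held fixed."""

    phi: float
    log_likelihood_at_phi: float
    at_boundary: bool = False
    flat: bool = False


def mixture_mean(beta: np.ndarray, design: GeneDesign) -> np.ndarray:
    """Per-spot mean maternal probability under the mixture-of-expit model."""
    eta = np.clip(design.eta(beta), -ETA_CLIP, ETA_CLIP)
    return (design.A * expit(eta)).sum(axis=1)


def loglik(beta: np.ndarray, phi: float, design: GeneDesign) -> float:
    p = mixture_mean(beta, design)
    f, _, _ = _bb_terms(design.y, design.n, p, phi, order=0)
    return float(f.sum())


def loglik_grad_hess(
    beta: np.ndarray, phi: float, design: GeneDesign
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood with exact analytic gradient and Hessian in beta.

    Chain rule: with u_k = alpha_k * sigma'(eta_k) and
    v_k = alpha_k * sigma''(eta_k), the spot-level derivative of p in the
    parameters is G = sum_k u_k * (d eta_k / d beta), and

        grad = G' f1,    H = G' diag(f2) G + sum_k M_k' diag(f1 v_k) M_k,

    where f1, f2 are the log-pmf derivatives in p (digamma/trigamma).
    """
    eta = np.clip(design.eta(beta), -ETA_CLIP, ETA_CLIP)
    sig = expit(eta)
    p = (design.A * sig).sum(axis=1)
    f, f1, f2 = _bb_terms(design.y, design.n, p, phi, order=2)
    if not np.isfinite(f).all():
        bad = int(np.flatnonzero(~np.isfinite(f))[0])
        raise FloatingPointError(f"non-finite log-likelihood term at spot index {bad}")
    sp = sig * (1 - sig)
    u = design.A * sp                    # S x K
    v = design.A * sp * (1 - 2 * sig)    # S x K
    M = design.param_jacobian()          # K x S x P
    G = np.einsum("sk,ksp->sp", u, M)
    grad = G.T @ f1
    H = G.T @ (f2[:, None] * G)
    H += np.einsum("ksp,ks,ksq->pq", M, f1[None, :] * v.T, M)
    H = 0.5 * (H + H.T)
    return float(f.sum()), grad, H


def estimate_phi(
    beta: np.ndarray,
    design: GeneDesign,
    bounds: tuple[float, float] = PHI_BOUNDS,
) -> OverdispersionEstimate:
    """Maximize the gene log-likelihood over phi with beta fixed.

    Deterministic bounded scalar optimization. When every usable spot has
    n = 1 the likelihood is flat in phi (a single allele-resolved
    transcript carries no overdispersion information) and the result is
    flagged ``flat``; boundary solutions are flagged ``at_boundary``.
    """
    p = mixture_mean(beta, design)
    y, n = design.y, design.n

    def negll(phi: float) -> float:
        f, _, _ = _bb_terms(y, n, p, phi, order=0)
        return -float(f.sum())

    lo, hi = bounds
    flat = bool((n <= 1).all())
    if flat:
        ll = -negll(lo)
        return OverdispersionEstimate(lo, ll, at_boundary=True, flat=True)
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    phi = float(res.x)
    at_boundary = phi - lo < 1e-5 * (hi - lo) or hi - phi < 1e-5 * (hi - lo)
    return OverdispersionEstimate(phi, -float(res.fun), at_boundary=at_boundary, flat=False)


def phi_moment_estimate(y: np.ndarray, n: np.ndarray) -> float:
    """Method-of-moments warm start for phi, clipped to the fitting bounds.

    Under the model, E[(y - n p)^2] = n p (1-p) (1 + (n-1) phi); solving
    the averaged relation with the pooled p gives a cheap initial value.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    y, n = y[use], n[use]
    p = y.sum() / n.sum()
    if p <= 0 or p >= 1 or (n <= 1).all():
        return PHI_BOUNDS[0]
    s = (y - n * p) ** 2 / (n * p * (1 - p))
    denom = (n - 1).mean()
    phi = (s.mean() - 1.0) / denom if denom > 0 else 0.0
    return float(np.clip(phi, *PHI_BOUNDS))
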