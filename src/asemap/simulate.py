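"""Synthetic data generation and the parameter-recovery evaluation harness.

The generator emulates the salient structure of allele-resolved spatial
transcriptomics: spots scattered over a planar section, spatially
clustered cell types (broad "granule-like" layouts vs. narrower ones),
smooth ground-truth maternal-probability surfaces drawn as random linear
combinations of a low-rank thin-plate spline basis assigned to one cell
type, and beta-binomial count sampling with a gene-level total UMI budget
allocated multinomially over spots. The evaluation harness computes the
Pearson correlation between estimated and true probability surfaces and
the RMSE of the logit-scale coefficients, over a factorial grid of UMI
bins and overdispersion values.

All randomness flows through per-replicate child seeds spawned from a
master seed, so grids are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit

from .data_model import (
    CellTypeWeights,
    ExpressionRates,
    SpatialAllelicCounts,
    write_allelic_counts,
)
from .fitter import FitOptions, GeneFit, fit_gene, make_design
from .mixture import default_rates
from .spline import SplineBasis, build_tps_basis

__all__ = [
    "SimulationTruth",
    "gen_landscape",
    "gen_truth_surface",
    "sample_counts",
    "evaluate_fit",
    "run_simulation_grid",
    "write_bundle",
]

DEFAULT_UMI_BINS: tuple[tuple[int, int], ...] = ((100, 500), (500, 1000), (1000, 10000))


@dataclass
class SimulationTruth:
    """Ground truth for one simulated gene on one landscape."""

    coords: np.ndarray
    weights: CellTypeWeights
    mu: np.ndarray  # K-vector of per-cell-type expression rates
    basis: SplineBasis
    beta_by_ct: dict  # cell type -> (intercept, L-vector of spline coefs)
    p_true: np.ndarray
    ase_cell_type: str
    phi_true: float = np.nan
    total_umi: int = 0
    seed: int = 0

    @property
    def cell_types(self) -> np.ndarray:
        return self.weights.cell_types

    def _fit_cell_types(self, fit: GeneFit) -> list[str]:
        """Map a fit's cell-type labels onto truth labels.

        A pooled (single-cell-type) fit of a truth whose pattern is shared
        by all cell types is equivalent to any one of them.
        """
        cts = [str(c) for c in fit.cell_types]
        known = set(map(str, self.weights.cell_types))
        if all(c in known for c in cts):
            return cts
        if len(cts) == 1 and self.ase_cell_type == "all":
            return [str(self.weights.cell_types[0])]
        raise KeyError(f"fit cell types {cts} not present in simulation truth")

    def beta_for_fit(self, fit: GeneFit) -> np.ndarray:
        """Truth coefficients arranged in a fit's parameter layout."""
        cts = self._fit_cell_types(fit)
        K = len(cts)
        intercepts = [self.beta_by_ct[c][0] for c in cts]
        if fit.shared_spline:
            # shared layout is exact when all cell types carry the same coefs
            coefs = self.beta_by_ct[cts[0]][1]
            return np.concatenate([intercepts, coefs])
        mask = fit.design_info.get("spline_cts")
        mask = np.ones(K, dtype=bool) if mask is None else np.asarray(mask, bool)
        blocks = [self.beta_by_ct[c][1] for c, m in zip(cts, mask) if m]
        return np.concatenate([intercepts] + blocks)


def gen_landscape(
    S: int,
    K: int,
    layout: str = "blobs",
    seed: int = 0,
) -> tuple[np.ndarray, CellTypeWeights]:
    """Spot coordinates plus spatially structured cell-type weights.

    Layouts: ``bands`` (soft vertical stripes, one per cell type),
    ``blobs`` (softmax of smooth random fields — clustered types with
    varying footprint), ``uniform`` (every spot exactly 1/K per type).
    """
    if S < 100:
        raise ValueError("need at least 100 spots")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(S, 2))
    if layout == "uniform":
        W = np.full((S, K), 1.0 / K)
    elif layout == "bands":
        centers = (np.arange(K) + 0.5) / K
        width = 0.5 / K
        logits = -((coords[:, 0][:, None] - centers[None, :]) ** 2) / (2 * width**2)
        W = np.exp(logits - logits.max(axis=1, keepdims=True))
        W /= W.sum(axis=1, keepdims=True)
    elif layout == "blobs":
        n_bumps, ell = 6, 0.25
        F = np.zeros((S, K))
        for k in range(K):
            amp = rng.normal(size=n_bumps)
            ctr = rng.uniform(0, 1, size=(n_bumps, 2))
            d2 = ((coords[:, None, :] - ctr[None, :, :]) ** 2).sum(axis=2)
            F[:, k] = (amp[None, :] * np.exp(-d2 / (2 * ell**2))).sum(axis=1)
        logits = 3.0 * F
        W = np.exp(logits - logits.max(axis=1, keepdims=True))
        W /= W.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    spot_ids = np.array([f"s{i:05d}" for i in range(S)], dtype=object)
    cts = np.array([f"ct{k+1}" for k in range(K)], dtype=object)
    return coords, CellTypeWeights(spot_ids=spot_ids, cell_types=cts, W=W)


def gen_truth_surface(
    coords: np.ndarray,
    weights: CellTypeWeights,
    k: int = 5,
    coef_scale: float = 1.0,
    intercept: float = 0.0,
    ase_cell_type: str | None = None,
    mu: np.ndarray | None = None,
    seed: int = 0,
) -> SimulationTruth:
    """Random smooth ground-truth surface for one cell type.

    Spline coefficients for the designated cell type are drawn from a
    zero-mean normal with standard deviation ``coef_scale`` on the logit
    scale, on top of a fixed ``intercept`` (default 0, i.e. balanced);
    other cell types sit at p = 0.5 (all coefficients zero).
    ``ase_cell_type="all"`` gives every cell type the same drawn
    coefficients, so the mixture is independent of the weights.
    ``coef_scale=0`` is the global null (p = 0.5 everywhere).
    """
    rng = np.random.default_rng(seed)
    basis = build_tps_basis(coords, k=k)
    K = weights.n_cell_types
    if ase_cell_type is None:
        ase_cell_type = str(weights.cell_types[0])
    coefs = rng.normal(0.0, coef_scale, size=basis.L) if coef_scale > 0 else np.zeros(basis.L)
    beta_by_ct: dict[str, tuple[float, np.ndarray]] = {}
    for ct in weights.cell_types:
        if ase_cell_type == "all" or str(ct) == ase_cell_type:
            beta_by_ct[str(ct)] = (intercept, coefs.copy())
        else:
            beta_by_ct[str(ct)] = (0.0, np.zeros(basis.L))
    mu = np.ones(K) if mu is None else np.asarray(mu, dtype=float)
    raw = weights.W * mu[None, :]
    A = raw / raw.sum(axis=1, keepdims=True)
    eta = np.stack(
        [beta_by_ct[str(ct)][0] + basis.design @ beta_by_ct[str(ct)][1]
         for ct in weights.cell_types],
        axis=1,
    )
    p_true = (A * expit(eta)).sum(axis=1)
    return SimulationTruth(
        coords=coords,
        weights=weights,
        mu=mu,
        basis=basis,
        beta_by_ct=beta_by_ct,
        p_true=p_true,
        ase_cell_type=ase_cell_type,
        seed=seed,
    )


def sample_counts(
    truth: SimulationTruth,
    total_umi: int,
    phi: float,
    seed: int = 0,
    gene_id: str = "g1",
    sample_id: str = "sim",
) -> SpatialAllelicCounts:
    """Draw one gene's counts from the ground-truth distribution.

    The gene's ``total_umi`` transcripts are allocated over spots by a
    multinomial with probabilities proportional to sum_k W[i,k] mu[k];
    maternal counts are beta-binomial draws around p_true (binomial when
    phi = 0).
    """
    if total_umi < 1:
        raise ValueError("total_umi must be at least 1")
    if not 0 <= phi < 1:
        raise ValueError("phi must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expr = truth.weights.W @ truth.mu
    probs = expr / expr.sum()
    N = rng.multinomial(total_umi, probs)
    Y = np.zeros_like(N)
    pos = N > 0
    if phi == 0:
        Y[pos] = rng.binomial(N[pos], truth.p_true[pos])
    else:
        c = (1 - phi) / phi
        q = rng.beta(truth.p_true[pos] * c, (1 - truth.p_true[pos]) * c)
        Y[pos] = rng.binomial(N[pos], q)
    truth.phi_true = phi
    truth.total_umi = total_umi
    S = len(N)
    return SpatialAllelicCounts(
        spot_ids=truth.weights.spot_ids,
        gene_ids=np.array([gene_id], dtype=object),
        Y=sparse.csr_matrix(Y.reshape(S, 1)),
        N=sparse.csr_matrix(N.reshape(S, 1)),
        coords=truth.coords,
        sample_id=sample_id,
    )


def evaluate_fit(fit: GeneFit, truth: SimulationTruth) -> tuple[float, float]:
    """(Pearson r of surfaces at the spots, RMSE of logit-scale coefficients).

    The estimated surface is the fit's mixture mean evaluated at every
    spot of the truth landscape; r is undefined (NaN) when the estimated
    surface is constant.
    """
    cts = truth._fit_cell_types(fit)
    order = [list(map(str, truth.weights.cell_types)).index(c) for c in cts]
    mu = truth.mu[order]
    raw = truth.weights.W[:, order] * mu[None, :]
    if len(cts) < truth.weights.n_cell_types and truth.ase_cell_type == "all":
        A = np.ones((truth.weights.W.shape[0], len(cts)))
    else:
        A = raw / raw.sum(axis=1, keepdims=True)
    from .surface import _grid_jacobian

    B = truth.basis.design if fit.beta_hat.size > len(cts) else np.zeros(
        (truth.coords.shape[0], 0)
    )
    J = _grid_jacobian(fit, B)
    eta = np.stack([J[k] @ fit.beta_hat for k in range(len(cts))], axis=1)
    p_hat = (A * expit(eta)).sum(axis=1)
    if np.std(p_hat) < 1e-12 or np.std(truth.p_true) < 1e-12:
        r = np.nan
    else:
        r = float(np.corrcoef(p_hat, truth.p_true)[0, 1])
    beta_true = truth.beta_for_fit(fit)
    rmse = float(np.sqrt(np.mean((fit.beta_hat - beta_true) ** 2)))
    return r, rmse


def run_simulation_grid(
    S: int = 2000,
    K: int = 2,
    layouts: Sequence[str] = ("blobs",),
    umi_bins: Sequence[tuple[int, int]] = DEFAULT_UMI_BINS,
    phi_values: Sequence[float] = (0.1,),
    replicates: int = 20,
    k: int = 5,
    coef_scale: float = 1.0,
    ase_cell_type: str | None = None,
    shared_spline: bool = False,
    master_seed: int = 0,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Generate -> sample -> fit -> evaluate over a factorial grid.

    One row per replicate with all factors, the surface correlation r,
    the coefficient RMSE, and the convergence flag; per-replicate
    failures are recorded and the grid continues.
    """
    ss = np.random.SeedSequence(master_seed)
    rows = []
    for layout in layouts:
        for lo, hi in umi_bins:
            for phi in phi_values:
                for rep in range(replicates):
                    child = ss.spawn(1)[0]
                    seeds = child.generate_state(3)
                    row = {
                        "layout": layout, "S": S, "K": K, "umi_bin": f"{lo}-{hi}",
                        "phi": phi, "replicate": rep,
                    }
                    try:
                        coords, W = gen_landscape(S, K, layout, seed=seeds[0])
                        truth = gen_truth_surface(
                            coords, W, k=k, coef_scale=coef_scale,
                            ase_cell_type=ase_cell_type, seed=seeds[1],
                        )
                        rng = np.random.default_rng(seeds[2])
                        umi = int(rng.integers(lo, hi + 1))
                        counts = sample_counts(truth, umi, phi, seed=seeds[2])
                        use_mixture = truth.ase_cell_type != "all" and K > 1
                        design = make_design(
                            counts, "g1",
                            weights=W if use_mixture else None,
                            covariates=truth.basis,
                            shared_spline=shared_spline if use_mixture else True,
                            ct_share_floor=1.0,
                        )
                        fit = fit_gene(design, options)
                        r, rmse = evaluate_fit(fit, truth)
                        row.update(
                            total_umi=umi, r=r, rmse_beta=rmse,
                            phi_hat=fit.phi_hat, converged=fit.converged, error="",
                        )
                    except Exception as e:
                        row.update(
                            total_umi=np.nan, r=np.nan, rmse_beta=np.nan,
                            phi_hat=np.nan, converged=False, error=str(e),
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(
    truth: SimulationTruth, counts: SpatialAllelicCounts, outdir: str | Path
) -> None:
    """Write a dataset bundle (MTX counts, coords, weights, rates, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_allelic_counts(counts, outdir)
    w = truth.weights
    df = pd.DataFrame(w.W, columns=w.cell_types)
    df.insert(0, "spot_id", w.spot_ids)
    df.to_csv(outdir / "weights.csv", index=False)
    rates = [
        {"gene": str(g), "cell_type": str(ct), "rate": float(truth.mu[k])}
        for g in counts.gene_ids
        for k, ct in enumerate(w.cell_types)
    ]
    pd.DataFrame(rates).to_csv(outdir / "rates.csv", index=False)
    payload = {
        "ase_cell_type": truth.ase_cell_type,
        "phi_true": truth.phi_true,
        "total_umi": truth.total_umi,
        "seed": int(truth.seed),
        "beta_by_ct": {
            c: {"intercept": b0, "coefs": list(map(float, cf))}
            for c, (b0, cf) in truth.beta_by_ct.items()
        },
        "p_true": truth.p_true.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(payload))
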