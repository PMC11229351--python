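"""Hypothesis tests for allelic imbalance, FDR control, and gene classification.

Four categories of allele-specific expression (ASE) are tested per gene:

1. overall bias — logit(p) = beta0 ignoring cell type and space; Wald
   test of beta0 != 0. A significant gene is called maternal only when
   the estimated maternal probability exceeds 0.6, paternal only when it
   is below 0.4.
2. within-cell-type bias — p_i = sum_k alpha[i,k] expit(beta0_k); Wald
   test per cell-type intercept, same direction rule on expit(beta0_k).
3. overall spatial pattern — likelihood ratio test of the thin-plate
   spline terms over the intercept-only model (overdispersion
   re-estimated in each model), chi-square with df = L.
4. within-cell-type spatial pattern — the mixture model with cell-type
   intercepts plus spline terms inside the expit, LRT against the
   within-cell-type intercept model; by default the spline coefficients
   are shared across cell types (df = L), optionally cell-type-specific
   (one test per cell type, df = L each).

Benjamini-Hochberg correction is applied within each category (and
within cell type for the within-cell-type categories); significance at
q < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .betabinom import GeneDesign
from .data_model import (
    CellTypeWeights,
    ExpressionRates,
    SpatialAllelicCounts,
    filter_genes_overall,
    filter_genes_within_celltype,
)
from .fitter import FitOptions, GeneFit, fit_gene, make_design
from .spline import SplineBasis, build_tps_basis

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "test_overall_bias",
    "test_within_ct_bias",
    "test_overall_spatial",
    "test_within_ct_spatial",
    "adjust_fdr",
    "classify_genes",
    "run_test_battery",
    "CATEGORIES",
    "SUMMARY_ROWS",
]

CATEGORIES = ("overall_bias", "within_ct_bias", "overall_spatial", "within_ct_spatial")

SUMMARY_ROWS = (
    "no significant ASE",
    "overall maternal bias",
    "overall paternal bias",
    "within cell type maternal bias",
    "within cell type paternal bias",
    "overall spatial pattern",
    "within cell type spatial pattern",
)


@dataclass
class TestResult:
    """One hypothesis-test outcome for one gene (and possibly cell type)."""

    gene_id: str
    category: str
    cell_type: str | None
    statistic: float
    df: int
    p_value: float
    q_value: float = np.nan
    direction: str = "none"
    p_hat: float = np.nan
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "category": self.category,
            "cell_type": self.cell_type,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "q": self.q_value,
            "direction": self.direction,
            "p_hat": self.p_hat,
            "warnings": "; ".join(self.warnings),
        }


def _wald_p(est: float, se: float) -> tuple[float, float]:
    if se <= 0 or not np.isfinite(se):
        return np.nan, np.nan
    z = est / se
    return z, 2.0 * stats.norm.sf(abs(z))


def _safe_fit(design: GeneDesign, options: FitOptions | None) -> GeneFit | None:
    try:
        return fit_gene(design, options)
    except Exception as e:
        logger.warning("fit failed for gene %s: %s", design.gene_id, e)
        return None


def test_overall_bias(
    counts: SpatialAllelicCounts,
    gene_id: str,
    options: FitOptions | None = None,
) -> TestResult:
    """Wald test of a constant allelic bias, ignoring cell type and space."""
    design = make_design(counts, gene_id)
    fit = _safe_fit(design, options)
    if fit is None:
        return TestResult(gene_id, "overall_bias", None, np.nan, 1, np.nan,
                          warnings=["fit failed"])
    b0, se = fit.beta_hat[0], fit.se[0]
    z, p = _wald_p(b0, se)
    from scipy.special import expit

    return TestResult(
        gene_id, "overall_bias", None, z, 1, p, p_hat=float(expit(b0)),
        warnings=list(fit.warnings),
    )


def test_within_ct_bias(
    counts: SpatialAllelicCounts,
    gene_id: str,
    weights: CellTypeWeights,
    rates: ExpressionRates | None = None,
    cell_types: Sequence[str] | None = None,
    options: FitOptions | None = None,
) -> list[TestResult]:
    """Per-cell-type Wald tests of the mixture-model intercepts."""
    from scipy.special import expit

    design = make_design(counts, gene_id, weights=weights, rates=rates)
    fit = _safe_fit(design, options)
    if fit is None:
        return [
            TestResult(gene_id, "within_ct_bias", None, np.nan, 1, np.nan,
                       warnings=["fit failed"])
        ]
    wanted = None if cell_types is None else {str(c) for c in cell_types}
    out = []
    for k, ct in enumerate(fit.cell_types):
        if wanted is not None and str(ct) not in wanted:
            continue
        z, p = _wald_p(fit.beta_hat[k], fit.se[k])
        out.append(
            TestResult(
                gene_id, "within_ct_bias", str(ct), z, 1, p,
                p_hat=float(expit(fit.beta_hat[k])), warnings=list(fit.warnings),
            )
        )
    return out


def _lrt(ll_full: float, ll_null: float, df: int) -> tuple[float, float, list[str]]:
    stat = 2.0 * (ll_full - ll_null)
    warnings = []
    if stat < 0:
        warnings.append(f"LRT statistic floored at 0 (was {stat:.3g})")
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df)) if df > 0 else 1.0, warnings


def test_overall_spatial(
    counts: SpatialAllelicCounts,
    gene_id: str,
    basis: SplineBasis,
    options: FitOptions | None = None,
) -> TestResult:
    """LRT of spline spatial terms over the intercept-only model (no mixture)."""
    d_null = make_design(counts, gene_id)
    d_full = make_design(counts, gene_id, covariates=basis)
    f_null = _safe_fit(d_null, options)
    f_full = _safe_fit(d_full, options)
    if f_null is None or f_full is None:
        return TestResult(gene_id, "overall_spatial", None, np.nan, basis.L, np.nan,
                          warnings=["fit failed"])
    stat, p, w = _lrt(f_full.loglik, f_null.loglik, d_full.L)
    return TestResult(
        gene_id, "overall_spatial", None, stat, d_full.L, p,
        warnings=w + list(f_full.warnings),
    )


def test_within_ct_spatial(
    counts: SpatialAllelicCounts,
    gene_id: str,
    weights: CellTypeWeights,
    basis: SplineBasis,
    rates: ExpressionRates | None = None,
    shared_spline: bool = True,
    options: FitOptions | None = None,
) -> list[TestResult]:
    """LRT of spatial terms in the cell-type mixture model.

    With ``shared_spline`` (default) a single test of the common spline
    block; otherwise one test per cell type, dropping that cell type's
    spline block in the null.
    """
    d_null = make_design(counts, gene_id, weights=weights, rates=rates)
    f_null = _safe_fit(d_null, options)
    if f_null is None:
        return [
            TestResult(gene_id, "within_ct_spatial", None, np.nan, basis.L, np.nan,
                       warnings=["fit failed"])
        ]
    if shared_spline:
        d_full = make_design(counts, gene_id, weights=weights, rates=rates,
                             covariates=basis, shared_spline=True)
        f_full = _safe_fit(d_full, options)
        if f_full is None:
            return [
                TestResult(gene_id, "within_ct_spatial", None, np.nan, basis.L,
                           np.nan, warnings=["fit failed"])
            ]
        stat, p, w = _lrt(f_full.loglik, f_null.loglik, d_full.L)
        return [
            TestResult(gene_id, "within_ct_spatial", None, stat, d_full.L, p,
                       warnings=w + list(f_full.warnings))
        ]
    # cell-type-specific spline terms: full model has one block per cell type;
    # each test removes one block
    d_full = make_design(counts, gene_id, weights=weights, rates=rates,
                         covariates=basis, shared_spline=False)
    f_full = _safe_fit(d_full, options)
    if f_full is None:
        return [
            TestResult(gene_id, "within_ct_spatial", None, np.nan, basis.L, np.nan,
                       warnings=["fit failed"])
        ]
    out = []
    K = len(d_full.cell_types)
    for k, ct in enumerate(d_full.cell_types):
        mask = np.ones(K, dtype=bool)
        mask[k] = False
        d_red = make_design(counts, gene_id, weights=weights, rates=rates,
                            covariates=basis, shared_spline=False, spline_cts=mask)
        f_red = _safe_fit(d_red, options)
        if f_red is None:
            out.append(
                TestResult(gene_id, "within_ct_spatial", str(ct), np.nan, basis.L,
                           np.nan, warnings=["fit failed"])
            )
            continue
        stat, p, w = _lrt(f_full.loglik, f_red.loglik, d_full.L)
        out.append(
            TestResult(gene_id, "within_ct_spatial", str(ct), stat, d_full.L, p,
                       warnings=w + list(f_full.warnings))
        )
    return out


# ---------------------------------------------------------------------------
# FDR and classification


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate to NaN outputs (with a log note) and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.all():
        logger.warning("adjust_fdr: %d NaN p-values propagated", int((~ok).sum()))
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(adjusted, 1.0)
    q[ok] = qv
    return q


def _apply_direction(df: pd.DataFrame, q_cutoff: float,
                     maternal_above: float = 0.6, paternal_below: float = 0.4) -> None:
    bias = df["category"].isin(["overall_bias", "within_ct_bias"])
    sig = df["q"] < q_cutoff
    df.loc[:, "direction"] = "none"
    df.loc[bias & sig & (df["p_hat"] > maternal_above), "direction"] = "maternal"
    df.loc[bias & sig & (df["p_hat"] < paternal_below), "direction"] = "paternal"


def run_test_battery(
    counts: SpatialAllelicCounts,
    weights: CellTypeWeights | None = None,
    rates: ExpressionRates | None = None,
    gene_ids: Sequence[str] | None = None,
    categories: Sequence[str] = CATEGORIES,
    k: int = 5,
    basis: SplineBasis | None = None,
    min_nonzero: int = 128,
    presence_threshold: float = 0.5,
    q_cutoff: float = 0.01,
    shared_spline: bool = True,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Run the requested test categories over all filter-passing genes.

    Returns a tidy frame (gene, category, cell_type, statistic, df, p, q,
    direction, p_hat, warnings) with BH correction applied within each
    category, and within cell type for the within-cell-type categories.
    """
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    overall_genes = filter_genes_overall(counts, min_nonzero)
    if gene_ids is not None:
        requested = {str(g) for g in gene_ids}
        overall_genes = [g for g in overall_genes if g in requested]
    within = {}
    if weights is not None and (
        "within_ct_bias" in categories or "within_ct_spatial" in categories
    ):
        within = filter_genes_within_celltype(
            counts, weights, min_nonzero, presence_threshold
        )
        if gene_ids is not None:
            within = {ct: [g for g in gs if g in requested] for ct, gs in within.items()}

    need_basis = "overall_spatial" in categories or "within_ct_spatial" in categories
    if need_basis and basis is None:
        basis = build_tps_basis(counts.coords, k=k)

    results: list[TestResult] = []
    if "overall_bias" in categories:
        for g in overall_genes:
            results.append(test_overall_bias(counts, g, options))
    if "overall_spatial" in categories:
        for g in overall_genes:
            results.append(test_overall_spatial(counts, g, basis, options))
    if weights is not None and "within_ct_bias" in categories:
        gene_to_cts: dict[str, list[str]] = {}
        for ct, genes in within.items():
            for g in genes:
                gene_to_cts.setdefault(g, []).append(ct)
        for g, cts in gene_to_cts.items():
            results.extend(
                test_within_ct_bias(counts, g, weights, rates, cell_types=cts,
                                    options=options)
            )
    if weights is not None and "within_ct_spatial" in categories:
        genes_any_ct = sorted({g for gs in within.values() for g in gs})
        for g in genes_any_ct:
            results.extend(
                test_within_ct_spatial(counts, g, weights, basis, rates,
                                       shared_spline=shared_spline, options=options)
            )

    df = pd.DataFrame([r.as_dict() for r in results])
    if df.empty:
        return df
    # BH within category; within-cell-type categories additionally per cell type
    df["q"] = np.nan
    for cat, sub in df.groupby("category"):
        if cat.startswith("within_ct") and sub["cell_type"].notna().any():
            for ct, sub2 in sub.groupby("cell_type", dropna=False):
                df.loc[sub2.index, "q"] = adjust_fdr(sub2["p"].to_numpy())
        else:
            df.loc[sub.index, "q"] = adjust_fdr(sub["p"].to_numpy())
    _apply_direction(df, q_cutoff)
    return df


def classify_genes(
    results: pd.DataFrame,
    q_cutoff: float = 0.01,
    chromosome_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tally genes into the seven-row ASE taxonomy.

    Genes may belong to several categories; "no significant ASE" is
    exclusive (genes in no other row). When ``chromosome_map`` is given,
    autosomal and X-chromosome genes are counted separately.
    """
    if results.empty:
        return pd.DataFrame(columns=["category", "n_genes"])
    sig = results[results["q"] < q_cutoff]
    membership: dict[str, set[str]] = {row: set() for row in SUMMARY_ROWS}
    membership["overall maternal bias"] = set(
        sig[(sig["category"] == "overall_bias") & (sig["direction"] == "maternal")]["gene"]
    )
    membership["overall paternal bias"] = set(
        sig[(sig["category"] == "overall_bias") & (sig["direction"] == "paternal")]["gene"]
    )
    membership["within cell type maternal bias"] = set(
        sig[(sig["category"] == "within_ct_bias") & (sig["direction"] == "maternal")]["gene"]
    )
    membership["within cell type paternal bias"] = set(
        sig[(sig["category"] == "within_ct_bias") & (sig["direction"] == "paternal")]["gene"]
    )
    membership["overall spatial pattern"] = set(
        sig[sig["category"] == "overall_spatial"]["gene"]
    )
    membership["within cell type spatial pattern"] = set(
        sig[sig["category"] == "within_ct_spatial"]["gene"]
    )
    all_genes = set(results["gene"])
    any_sig = set().union(*membership.values())
    membership["no significant ASE"] = all_genes - any_sig

    def _counts(genes: set[str]) -> dict:
        if chromosome_map is None:
            return {"n_genes": len(genes)}
        x = sum(1 for g in genes if chromosome_map.get(g) == "X")
        return {"n_autosomal": len(genes) - x, "n_x": x}

    rows = [{"category": row, **_counts(membership[row])} for row in SUMMARY_ROWS]
    return pd.DataFrame(rows)
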