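"""Per-gene cell-type contribution shares (mixture weights).

The share of gene j's transcripts at spot i attributable to cell type k is

    alpha[i, k] = w[i, k] * mu[i, j, k] / sum_k w[i, k] * mu[i, j, k],

combining deconvolution proportions w with cell-type-specific expression
rates mu. Spots where the denominator is zero (no cell type present that
expresses the gene) have an undefined conditional probability and are
marked invalid; they contribute nothing to the gene's likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CellTypeWeights, ExpressionRates, ValidationError

__all__ = ["MixtureWeights", "compute_alpha", "default_rates"]


@dataclass
class MixtureWeights:
    """Spot x cell-type contribution shares for one gene.

    Rows sum to 1 on spots where ``valid_mask`` is True; invalid spots
    (zero denominator) carry all-zero rows.
    """

    gene_id: str
    spot_ids: np.ndarray
    cell_types: np.ndarray
    A: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if (self.A < 0).any():
            raise ValidationError("negative mixture weights")
        if self.valid_mask.any():
            rowsum = self.A[self.valid_mask].sum(axis=1)
            if np.abs(rowsum - 1.0).max() > 1e-8:
                raise ValidationError("valid mixture rows must sum to 1")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.A, columns=self.cell_types)
        df.insert(0, "spot_id", self.spot_ids)
        df["valid"] = self.valid_mask
        df.to_csv(path, sep="\t", index=False)


def compute_alpha(
    weights: CellTypeWeights, rates: ExpressionRates, gene_id: str
) -> MixtureWeights:
    """Pre-compute the cell-type shares alpha for one gene.

    ``rates`` may be spatially constant (K-vector per gene) or spatially
    varying (S x K per gene, rows aligned with ``weights.spot_ids``).
    """
    gene_id = str(gene_id)
    if not np.array_equal(np.sort(weights.cell_types), np.sort(rates.cell_types)):
        raise ValidationError(
            "cell-type label sets of weights and rates disagree: "
            f"{sorted(weights.cell_types)} vs {sorted(rates.cell_types)}"
        )
    # align rate columns to the weight column order
    col = {c: i for i, c in enumerate(rates.cell_types)}
    perm = [col[c] for c in weights.cell_types]
    mu = rates.for_gene(gene_id)
    if mu.ndim == 1:
        mu = np.broadcast_to(mu[perm], weights.W.shape)
    else:
        if mu.shape[0] != weights.W.shape[0]:
            raise ValidationError(
                f"spatially varying rates for gene {gene_id!r} have "
                f"{mu.shape[0]} rows but weights have {weights.W.shape[0]} spots"
            )
        mu = mu[:, perm]
    if (mu < 0).any() or (weights.W < 0).any():
        raise ValidationError("negative rates or weights")
    raw = weights.W * mu
    denom = raw.sum(axis=1)
    valid = denom > 0
    A = np.zeros_like(raw)
    A[valid] = raw[valid] / denom[valid, None]
    return MixtureWeights(
        gene_id=gene_id,
        spot_ids=weights.spot_ids,
        cell_types=weights.cell_types,
        A=A,
        valid_mask=valid,
    )


def default_rates(
    gene_ids: Sequence[str], cell_types: Sequence[str]
) -> ExpressionRates:
    """Unit rates for every gene and cell type, so alpha equals w.

    The fallback when no upstream differential-expression estimates are
    supplied. With equal rates the shares reduce to the deconvolution
    proportions; if the truth had unequal rates, cell-type attribution of
    allelic signal is biased accordingly (demonstrated in the test suite).
    """
    gene_ids = [str(g) for g in gene_ids]
    cell_types = [str(c) for c in cell_types]
    ones = np.ones(len(cell_types))
    return ExpressionRates(
        gene_ids=np.array(gene_ids, dtype=object),
        cell_types=np.array(cell_types, dtype=object),
        rates={g: ones.copy() for g in gene_ids},
    )
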