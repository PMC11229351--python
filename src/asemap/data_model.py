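"""Typed containers for allele-resolved spatial count data and their I/O.

The central object is :class:`SpatialAllelicCounts`: per-spot, per-gene
maternal allele UMI counts ``Y`` and total allele-resolved counts ``N``
(both sparse), with 2D spot coordinates. Companion containers hold
per-spot cell-type proportions from an upstream deconvolution tool and
per-gene, per-cell-type expression rates from an upstream differential
expression tool. Loading intersects spot identifiers across sources
(conservative alignment — no zeros are fabricated for missing spots) and
validates the 0 <= Y <= N contract entry-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialAllelicCounts",
    "CellTypeWeights",
    "ExpressionRates",
    "ValidationError",
    "FormatError",
    "read_allelic_counts",
    "read_cell_type_weights",
    "read_expression_rates",
    "write_allelic_counts",
    "filter_genes_overall",
    "filter_genes_within_celltype",
    "merge_genes",
]


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


class FormatError(ValueError):
    """Raised for malformed input files (missing/duplicate identifiers etc.)."""


def _as_str_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    return np.array([str(v) for v in arr.ravel()], dtype=object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) == 0:
        raise FormatError(f"empty {what} set")
    uniq, counts = np.unique(ids, return_counts=True)
    if (counts > 1).any():
        dups = uniq[counts > 1][:5].tolist()
        raise FormatError(f"duplicate {what} identifiers: {dups}")


@dataclass
class SpatialAllelicCounts:
    """Maternal (Y) and total (N) allele-resolved UMI counts on a 2D lattice.

    Parameters
    ----------
    spot_ids : array of str, length S
    gene_ids : array of str, length G
    Y : scipy.sparse matrix, S x G
        Maternal allele UMI counts.
    N : scipy.sparse matrix, S x G
        Total allele-resolved UMI counts (maternal + paternal).
    coords : ndarray, S x 2
        Planar spot positions in arbitrary units.
    sample_id : str
        Label for the sample or puck.
    """

    spot_ids: np.ndarray
    gene_ids: np.ndarray
    Y: sparse.csr_matrix
    N: sparse.csr_matrix
    coords: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.spot_ids = _as_str_array(self.spot_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.Y = sparse.csr_matrix(self.Y)
        self.N = sparse.csr_matrix(self.N)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        S, G = len(self.spot_ids), len(self.gene_ids)
        if self.Y.shape != (S, G) or self.N.shape != (S, G):
            raise ValidationError(
                f"count matrix shapes {self.Y.shape}/{self.N.shape} do not match "
                f"{S} spots x {G} genes"
            )
        if self.coords.shape != (S, 2):
            raise ValidationError(f"coords shape {self.coords.shape} != ({S}, 2)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.gene_ids, "gene")
        if (self.Y.data < 0).any() or (self.N.data < 0).any():
            raise ValidationError("negative counts")
        # Y <= N entry-wise; the difference must have no positive entries.
        diff = (self.Y - self.N).tocoo()
        bad = diff.data > 0
        if bad.any():
            rows = diff.row[bad][:5]
            cols = diff.col[bad][:5]
            entries = [
                (str(self.spot_ids[r]), str(self.gene_ids[c]))
                for r, c in zip(rows, cols)
            ]
            raise ValidationError(f"Y > N at entries {entries}")

    def gene_vectors(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense (y, n) count vectors over all spots for one gene."""
        j = self.gene_index(gene_id)
        y = np.asarray(self.Y[:, j].todense()).ravel()
        n = np.asarray(self.N[:, j].todense()).ravel()
        return y, n

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == str(gene_id))
        if len(idx) == 0:
            raise KeyError(f"unknown gene {gene_id!r}")
        return int(idx[0])

    def subset_genes(self, gene_ids: Sequence[str]) -> "SpatialAllelicCounts":
        cols = [self.gene_index(g) for g in gene_ids]
        return SpatialAllelicCounts(
            spot_ids=self.spot_ids,
            gene_ids=self.gene_ids[cols],
            Y=self.Y[:, cols],
            N=self.N[:, cols],
            coords=self.coords,
            sample_id=self.sample_id,
        )


@dataclass
class CellTypeWeights:
    """Per-spot cell-type proportions from an upstream deconvolution tool.

    Rows are normalized to sum to 1 on construction; all entries must be
    nonnegative.
    """

    spot_ids: np.ndarray
    cell_types: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = _as_str_array(self.spot_ids)
        self.cell_types = _as_str_array(self.cell_types)
        self.W = np.asarray(self.W, dtype=float)
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.cell_types, "cell type")
        if self.W.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValidationError("weight matrix shape mismatch")
        if (self.W < 0).any():
            raise ValidationError("negative cell-type weights")
        rowsum = self.W.sum(axis=1)
        if (rowsum <= 0).any():
            raise ValidationError("spot with all-zero cell-type weights")
        if np.abs(rowsum - 1.0).max() > 1e-6:
            self.W = self.W / rowsum[:, None]

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def align_spots(self, spot_ids: Sequence[str]) -> "CellTypeWeights":
        order = {s: i for i, s in enumerate(self.spot_ids)}
        try:
            rows = [order[str(s)] for s in spot_ids]
        except KeyError as e:
            raise ValidationError(f"spot {e.args[0]!r} missing from weights") from e
        return CellTypeWeights(
            spot_ids=_as_str_array(spot_ids),
            cell_types=self.cell_types,
            W=self.W[rows],
        )


@dataclass
class ExpressionRates:
    """Expected expression rate of each gene per cell type.

    ``rates`` maps gene_id to either a K-vector (spatially constant) or an
    S x K matrix (spatially varying). A gene whose rates are all zero is
    invalid: no cell type could have produced its transcripts.
    """

    gene_ids: np.ndarray
    cell_types: np.ndarray
    rates: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_types = _as_str_array(self.cell_types)
        clean = {}
        for g in self.gene_ids:
            r = np.asarray(self.rates[g], dtype=float)
            if (r < 0).any():
                raise ValidationError(f"negative expression rate for gene {g!r}")
            if r.ndim == 1 and r.shape[0] != len(self.cell_types):
                raise ValidationError(f"rate vector length mismatch for gene {g!r}")
            if r.ndim == 2 and r.shape[1] != len(self.cell_types):
                raise ValidationError(f"rate matrix width mismatch for gene {g!r}")
            if not (r > 0).any():
                raise ValidationError(f"gene {g!r} has all-zero rates across cell types")
            clean[g] = r
        self.rates = clean

    def for_gene(self, gene_id: str) -> np.ndarray:
        return self.rates[str(gene_id)]


# ---------------------------------------------------------------------------
# Readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _read_mtx_with_sidecars(path: str | Path):
    """Read an MTX matrix with `<stem>.spots.tsv` / `<stem>.genes.tsv` sidecars."""
    path = Path(path)
    stem = path.with_suffix("")
    spots = pd.read_csv(f"{stem}.spots.tsv", sep="\t", header=None)[0]
    genes = pd.read_csv(f"{stem}.genes.tsv", sep="\t", header=None)[0]
    M = sparse.csr_matrix(mmread(path))
    if M.shape != (len(spots), len(genes)):
        raise FormatError(
            f"{path}: matrix shape {M.shape} does not match sidecars "
            f"({len(spots)} spots, {len(genes)} genes)"
        )
    return _as_str_array(spots), _as_str_array(genes), M


def _read_long_counts(path: str | Path):
    df = _read_table(path)
    required = {"spot_id", "gene", "maternal_count", "paternal_count"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: long-format counts need columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["gene"].isna().all() or len(df) == 0:
        raise FormatError(f"{path}: no gene rows")
    spots = _as_str_array(pd.unique(df["spot_id"].astype(str)))
    genes = _as_str_array(pd.unique(df["gene"].astype(str)))
    si = {s: i for i, s in enumerate(spots)}
    gi = {g: i for i, g in enumerate(genes)}
    rows = df["spot_id"].astype(str).map(si).to_numpy()
    cols = df["gene"].astype(str).map(gi).to_numpy()
    mat_counts = df["maternal_count"].to_numpy()
    pat_counts = df["paternal_count"].to_numpy()
    shape = (len(spots), len(genes))
    Y = sparse.coo_matrix((mat_counts, (rows, cols)), shape=shape).tocsr()
    N = sparse.coo_matrix((mat_counts + pat_counts, (rows, cols)), shape=shape).tocsr()
    return spots, genes, Y, N


def _read_coords(path: str | Path):
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for want in ("spot_id", "x1", "x2"):
        if want not in cols:
            raise FormatError(f"{path}: coordinates need columns spot_id, x1, x2")
    spots = _as_str_array(df[cols["spot_id"]])
    _check_unique(spots, "coordinate spot")
    xy = df[[cols["x1"], cols["x2"]]].to_numpy(dtype=float)
    return spots, xy


def read_allelic_counts(
    maternal_source: str | Path,
    total_source: str | Path | None,
    coords_source: str | Path,
    sample_id: str = "",
) -> SpatialAllelicCounts:
    """Load allele-resolved counts plus coordinates into a validated container.

    Two dialects are accepted:

    * a pair of Matrix Market files (maternal and total counts) each with
      ``<stem>.spots.tsv`` / ``<stem>.genes.tsv`` identifier sidecars, or
    * a single long-format CSV/TSV with columns
      ``spot_id, gene, maternal_count, paternal_count`` (pass it as
      ``maternal_source`` and set ``total_source=None`` or to the same path);
      total counts are maternal + paternal by definition.

    Spots are intersected across count and coordinate sources; dropped
    identifiers are logged, never zero-filled.
    """
    maternal_source = Path(maternal_source)
    if maternal_source.suffix.lower() == ".mtx":
        if total_source is None:
            raise FormatError("MTX input needs both a maternal and a total matrix")
        sy, gy, Y = _read_mtx_with_sidecars(maternal_source)
        sn, gn, N = _read_mtx_with_sidecars(total_source)
        if not np.array_equal(gy, gn):
            raise FormatError("maternal and total matrices disagree on gene identifiers")
        if not np.array_equal(sy, sn):
            raise FormatError("maternal and total matrices disagree on spot identifiers")
        spots, genes = sy, gy
    else:
        if total_source is not None and Path(total_source) != maternal_source:
            raise FormatError(
                "long-format input carries both alleles in one file; "
                "total_source must be None or the same path"
            )
        spots, genes, Y, N = _read_long_counts(maternal_source)

    cspots, xy = _read_coords(coords_source)
    keep = np.isin(spots, cspots)
    n_dropped_counts = int((~keep).sum())
    n_dropped_coords = int((~np.isin(cspots, spots)).sum())
    if n_dropped_counts or n_dropped_coords:
        logger.info(
            "spot intersection dropped %d count spots and %d coordinate spots",
            n_dropped_counts,
            n_dropped_coords,
        )
    if not keep.any():
        raise FormatError("no spots shared between counts and coordinates")
    spots = spots[keep]
    Y, N = Y[keep], N[keep]
    order = {s: i for i, s in enumerate(cspots)}
    xy = xy[[order[s] for s in spots]]
    return SpatialAllelicCounts(
        spot_ids=spots, gene_ids=genes, Y=Y, N=N, coords=xy, sample_id=sample_id
    )


def read_cell_type_weights(path: str | Path) -> CellTypeWeights:
    """Read a CSV/TSV with a spot_id column and one column per cell type."""
    df = _read_table(path)
    if "spot_id" not in df.columns:
        raise FormatError(f"{path}: weights need a spot_id column")
    ct = [c for c in df.columns if c != "spot_id"]
    if not ct:
        raise FormatError(f"{path}: no cell-type columns")
    return CellTypeWeights(
        spot_ids=_as_str_array(df["spot_id"]),
        cell_types=_as_str_array(ct),
        W=df[ct].to_numpy(dtype=float),
    )


def read_expression_rates(path: str | Path) -> ExpressionRates:
    """Read long-format rates: columns gene, cell_type, rate[, spot_id]."""
    df = _read_table(path)
    required = {"gene", "cell_type", "rate"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: rates need columns {sorted(required)}")
    cell_types = _as_str_array(pd.unique(df["cell_type"].astype(str)))
    ci = {c: i for i, c in enumerate(cell_types)}
    genes = _as_str_array(pd.unique(df["gene"].astype(str)))
    rates: dict[str, np.ndarray] = {}
    if "spot_id" in df.columns and df["spot_id"].notna().any():
        spots = _as_str_array(pd.unique(df["spot_id"].astype(str)))
        si = {s: i for i, s in enumerate(spots)}
        for g, sub in df.groupby("gene", sort=False):
            R = np.zeros((len(spots), len(cell_types)))
            R[
                sub["spot_id"].astype(str).map(si).to_numpy(),
                sub["cell_type"].astype(str).map(ci).to_numpy(),
            ] = sub["rate"].to_numpy()
            rates[str(g)] = R
    else:
        for g, sub in df.groupby("gene", sort=False):
            r = np.zeros(len(cell_types))
            r[sub["cell_type"].astype(str).map(ci).to_numpy()] = sub["rate"].to_numpy()
            rates[str(g)] = r
    return ExpressionRates(gene_ids=genes, cell_types=cell_types, rates=rates)


def write_allelic_counts(counts: SpatialAllelicCounts, outdir: str | Path) -> None:
    """Write the MTX-pair dialect (maternal.mtx, total.mtx, sidecars, coords.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, M in (("maternal", counts.Y), ("total", counts.N)):
        mmwrite(outdir / f"{name}.mtx", sparse.coo_matrix(M))
        pd.Series(counts.spot_ids).to_csv(
            outdir / f"{name}.spots.tsv", sep="\t", header=False, index=False
        )
        pd.Series(counts.gene_ids).to_csv(
            outdir / f"{name}.genes.tsv", sep="\t", header=False, index=False
        )
    pd.DataFrame(
        {"spot_id": counts.spot_ids, "x1": counts.coords[:, 0], "x2": counts.coords[:, 1]}
    ).to_csv(outdir / "coords.csv", index=False)


# ---------------------------------------------------------------------------
# Filters and gene merging


def filter_genes_overall(
    counts: SpatialAllelicCounts, min_nonzero: int = 128
) -> list[str]:
    """Genes measured in at least ``min_nonzero`` spots (N > 0)."""
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be positive")
    nnz = (counts.N > 0).sum(axis=0).A1
    return [str(g) for g in counts.gene_ids[nnz >= min_nonzero]]


def filter_genes_within_celltype(
    counts: SpatialAllelicCounts,
    weights: CellTypeWeights,
    min_nonzero: int = 128,
    presence_threshold: float = 0.5,
) -> dict[str, list[str]]:
    """Per cell type, genes with >= min_nonzero expressing spots containing it.

    A spot counts toward cell type k when its deconvolution weight
    W[i, k] >= ``presence_threshold``.
    """
    w = weights.align_spots(counts.spot_ids)
    nonzero = (counts.N > 0).astype(np.int8)
    out: dict[str, list[str]] = {}
    for k, ct in enumerate(w.cell_types):
        present = w.W[:, k] >= presence_threshold
        counts_per_gene = nonzero[present].sum(axis=0).A1 if present.any() else np.zeros(
            counts.n_genes
        )
        out[str(ct)] = [str(g) for g in counts.gene_ids[counts_per_gene >= min_nonzero]]
    return out


def merge_genes(
    counts: SpatialAllelicCounts,
    gene_set: Sequence[str],
    exclude: Sequence[str] = (),
    merged_id: str = "merged",
) -> SpatialAllelicCounts:
    """Sum maternal and total counts over a gene set into one pseudo-gene.

    Used e.g. to pool all X-chromosome genes (minus the inactivation marker
    itself) for a maximum-power chromosome-wide allelic profile.
    """
    excl = {str(g) for g in exclude}
    keep = [str(g) for g in gene_set if str(g) not in excl]
    if not keep:
        raise ValueError("no genes left to merge after exclusions")
    cols = [counts.gene_index(g) for g in keep]
    Y = counts.Y[:, cols].sum(axis=1)
    N = counts.N[:, cols].sum(axis=1)
    return SpatialAllelicCounts(
        spot_ids=counts.spot_ids,
        gene_ids=np.array([merged_id], dtype=object),
        Y=sparse.csr_matrix(Y),
        N=sparse.csr_matrix(N),
        coords=counts.coords,
        sample_id=counts.sample_id,
    )
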