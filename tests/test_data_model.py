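import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from asemap.data_model import (
    FormatError,
    SpatialAllelicCounts,
    ValidationError,
    filter_genes_overall,
    filter_genes_within_celltype,
    merge_genes,
    read_allelic_counts,
    write_allelic_counts,
)
from asemap.simulate import gen_landscape, gen_truth_surface, sample_counts

from conftest import make_counts


def _write_long(tmp_path, rows):
    df = pd.DataFrame(rows, columns=["spot_id", "gene", "maternal_count", "paternal_count"])
    p = tmp_path / "counts.csv"
    df.to_csv(p, index=False)
    return p


def _write_coords(tmp_path, spot_ids, coords=None):
    coords = np.zeros((len(spot_ids), 2)) if coords is None else coords
    p = tmp_path / "coords.csv"
    pd.DataFrame({"spot_id": spot_ids, "x1": coords[:, 0], "x2": coords[:, 1]}).to_csv(
        p, index=False
    )
    return p


class TestReaders:
    def test_long_format_total_is_maternal_plus_paternal(self, tmp_path):
        cp = _write_long(tmp_path, [("s1", "g1", 2, 3), ("s2", "g1", 0, 1)])
        xp = _write_coords(tmp_path, ["s1", "s2"])
        c = read_allelic_counts(cp, None, xp)
        assert c.Y[0, 0] == 2 and c.N[0, 0] == 5
        assert c.N[1, 0] == 1

    def test_empty_gene_set_is_format_error(self, tmp_path):
        p = tmp_path / "counts.csv"
        pd.DataFrame(columns=["spot_id", "gene", "maternal_count", "paternal_count"]).to_csv(
            p, index=False
        )
        xp = _write_coords(tmp_path, ["s1"])
        with pytest.raises(FormatError):
            read_allelic_counts(p, None, xp)

    def test_mtx_round_trip_reproduces_simulator_output(self, tmp_path):
        coords, W = gen_landscape(120, 2, "bands", seed=3)
        truth = gen_truth_surface(coords, W, k=5, seed=4)
        counts = sample_counts(truth, 800, 0.1, seed=5)
        write_allelic_counts(counts, tmp_path)
        back = read_allelic_counts(
            tmp_path / "maternal.mtx", tmp_path / "total.mtx", tmp_path / "coords.csv"
        )
        assert np.array_equal(back.spot_ids, counts.spot_ids)
        assert (back.Y != counts.Y).nnz == 0
        assert (back.N != counts.N).nnz == 0
        np.testing.assert_allclose(back.coords, counts.coords)

    def test_spot_intersection_drops_unshared(self, tmp_path):
        cp = _write_long(tmp_path, [("s1", "g1", 1, 1), ("s2", "g1", 2, 2)])
        xp = _write_coords(tmp_path, ["s1", "s3"])
        c = read_allelic_counts(cp, None, xp)
        assert list(c.spot_ids) == ["s1"]


class TestValidation:
    def test_y_exceeding_n_rejected_with_entry_names(self, rng):
        c = make_counts(rng)
        Y = c.Y.toarray()
        Y[3, 1] = c.N[3, 1] + 5
        with pytest.raises(ValidationError, match="Y > N"):
            SpatialAllelicCounts(c.spot_ids, c.gene_ids, Y, c.N, c.coords)

    def test_duplicate_spot_ids_rejected(self, rng):
        c = make_counts(rng, S=4)
        with pytest.raises(FormatError, match="duplicate"):
            SpatialAllelicCounts(
                ["a", "a", "b", "c"], c.gene_ids, c.Y, c.N, c.coords
            )

    def test_nonfinite_coords_rejected(self, rng):
        c = make_counts(rng)
        coords = c.coords.copy()
        coords[0, 0] = np.inf
        with pytest.raises(ValidationError, match="finite"):
            SpatialAllelicCounts(c.spot_ids, c.gene_ids, c.Y, c.N, coords)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_matrices_violating_y_le_n_always_rejected(self, seed):
        rng = np.random.default_rng(seed)
        S, G = 8, 4
        N = rng.integers(0, 6, size=(S, G))
        Y = rng.binomial(N, 0.5)
        i, j = rng.integers(0, S), rng.integers(0, G)
        Y[i, j] = N[i, j] + 1 + rng.integers(0, 3)
        with pytest.raises(ValidationError):
            SpatialAllelicCounts(
                [f"s{i}" for i in range(S)],
                [f"g{j}" for j in range(G)],
                sparse.csr_matrix(Y),
                sparse.csr_matrix(N),
                rng.uniform(size=(S, 2)),
            )


class TestFilters:
    def _counts_with_nnz(self, nnz_per_gene, S=200):
        rng = np.random.default_rng(0)
        G = len(nnz_per_gene)
        N = np.zeros((S, G), dtype=int)
        for j, m in enumerate(nnz_per_gene):
            N[rng.choice(S, size=m, replace=False), j] = 2
        Y = (N > 0).astype(int)
        return SpatialAllelicCounts(
            [f"s{i}" for i in range(S)],
            [f"g{j}" for j in range(G)],
            sparse.csr_matrix(Y),
            sparse.csr_matrix(N),
            rng.uniform(size=(S, 2)),
        )

    def test_threshold_boundary_128(self):
        c = self._counts_with_nnz([128, 127])
        assert filter_genes_overall(c, 128) == ["g0"]

    def test_threshold_one_keeps_any_expressed_gene(self):
        c = self._counts_with_nnz([128, 127, 0])
        assert filter_genes_overall(c, 1) == ["g0", "g1"]

    def test_monotone_in_threshold(self):
        c = self._counts_with_nnz([5, 50, 100, 150])
        prev = None
        for t in (1, 10, 60, 120, 160):
            kept = set(filter_genes_overall(c, t))
            if prev is not None:
                assert kept.issubset(prev)
            prev = kept

    def test_within_celltype_presence_rule(self, two_ct_weights):
        c = self._counts_with_nnz([200], S=200)
        # 130 spots have ct1 weight above threshold
        w1 = np.where(np.arange(200) < 130, 0.8, 0.2)
        w = two_ct_weights(c.spot_ids, w1)
        res = filter_genes_within_celltype(c, w, min_nonzero=128, presence_threshold=0.5)
        nnz_ct1 = ((c.N.toarray()[:130, 0] > 0)).sum()
        assert ("g0" in res["ct1"]) == (nnz_ct1 >= 128)

    def test_presence_threshold_zero_reduces_to_overall(self, two_ct_weights):
        c = self._counts_with_nnz([150, 100])
        w = two_ct_weights(c.spot_ids, np.full(200, 0.7))
        res = filter_genes_within_celltype(c, w, min_nonzero=128, presence_threshold=0.0)
        overall = filter_genes_overall(c, 128)
        assert res["ct1"] == overall and res["ct2"] == overall


class TestMergeGenes:
    def test_additivity_and_conservation(self, rng):
        c = make_counts(rng, S=30, G=4)
        merged = merge_genes(c, ["g0", "g1", "g2"], exclude=["g2"])
        expect_Y = c.Y[:, [0, 1]].sum(axis=1)
        assert np.array_equal(np.asarray(merged.Y.todense()).ravel(),
                              np.asarray(expect_Y).ravel())
        assert merged.N.sum() == c.N[:, [0, 1]].sum()
        np.testing.assert_allclose(merged.coords, c.coords)

    def test_single_gene_merge_is_identity(self, rng):
        c = make_counts(rng, S=30, G=2)
        merged = merge_genes(c, ["g1"])
        y0, n0 = c.gene_vectors("g1")
        y1, n1 = merged.gene_vectors("merged")
        assert np.array_equal(y0, y1) and np.array_equal(n0, n1)

    def test_empty_retained_set_errors(self, rng):
        c = make_counts(rng)
        with pytest.raises(ValueError):
            merge_genes(c, ["g0"], exclude=["g0"])
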