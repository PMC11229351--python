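import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from asemap.data_model import CellTypeWeights, SpatialAllelicCounts
from asemap.inference import (
    SUMMARY_ROWS,
    adjust_fdr,
    classify_genes,
    run_test_battery,
    test_overall_bias as overall_bias_test,
    test_overall_spatial as overall_spatial_test,
    test_within_ct_bias as within_ct_bias_test,
)
from asemap.simulate import gen_landscape, gen_truth_surface, sample_counts
from asemap.spline import build_tps_basis


def _single_gene_counts(y, n, coords=None, gene="g1"):
    S = len(y)
    rng = np.random.default_rng(0)
    coords = rng.uniform(size=(S, 2)) if coords is None else coords
    return SpatialAllelicCounts(
        spot_ids=[f"s{i}" for i in range(S)],
        gene_ids=[gene],
        Y=sparse.csr_matrix(np.asarray(y).reshape(-1, 1)),
        N=sparse.csr_matrix(np.asarray(n).reshape(-1, 1)),
        coords=coords,
    )


class TestAdjustFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_value_unchanged(self):
        assert adjust_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(adjust_fdr(np.ones(5)), np.ones(5))

    def test_nan_propagates(self):
        q = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.abs(adjust_fdr(p) - ref).max() < 1e-12

    def test_q_at_least_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 100)
        assert (adjust_fdr(p) >= p - 1e-15).all()


class TestBiasTests:
    def test_balanced_counts_not_significant(self):
        rng = np.random.default_rng(3)
        n = rng.integers(1, 10, 500)
        y = rng.binomial(n, 0.5)
        res = overall_bias_test(_single_gene_counts(y, n), "g1")
        assert res.p_value > 0.01
        assert abs(res.p_hat - 0.5) < 0.05

    def test_strong_maternal_bias_detected(self):
        rng = np.random.default_rng(4)
        n = rng.integers(2, 12, 500)
        y = rng.binomial(n, 0.85)
        res = overall_bias_test(_single_gene_counts(y, n), "g1")
        assert res.p_value < 1e-6
        assert res.p_hat > 0.8

    def test_within_ct_bias_isolates_the_biased_cell_type(self):
        rng = np.random.default_rng(5)
        S = 2000
        w1 = rng.uniform(0, 1, S)
        W = np.column_stack([w1, 1 - w1])
        p_spot = W @ np.array([0.9, 0.5])
        n = rng.integers(1, 10, S)
        y = rng.binomial(n, p_spot)
        counts = _single_gene_counts(y, n)
        weights = CellTypeWeights(spot_ids=counts.spot_ids,
                                  cell_types=["ct1", "ct2"], W=W)
        results = within_ct_bias_test(counts, "g1", weights)
        by_ct = {r.cell_type: r for r in results}
        assert by_ct["ct1"].p_value < 1e-4 and by_ct["ct1"].p_hat > 0.8
        assert by_ct["ct2"].p_value > 0.001
        assert abs(by_ct["ct2"].p_hat - 0.5) < 0.1

    def test_single_cell_type_reduces_to_overall(self):
        rng = np.random.default_rng(6)
        n = rng.integers(1, 8, 400)
        y = rng.binomial(n, 0.7)
        counts = _single_gene_counts(y, n)
        weights = CellTypeWeights(spot_ids=counts.spot_ids, cell_types=["only"],
                                  W=np.ones((400, 1)))
        r_ct = within_ct_bias_test(counts, "g1", weights)[0]
        r_all = overall_bias_test(counts, "g1")
        assert r_ct.p_hat == pytest.approx(r_all.p_hat, abs=1e-6)
        assert r_ct.statistic == pytest.approx(r_all.statistic, rel=1e-4)


class TestSpatialTests:
    def test_strong_surface_detected(self):
        coords, W = gen_landscape(1500, 1, "uniform", seed=7)
        truth = gen_truth_surface(coords, W, k=5, coef_scale=2.0, seed=8)
        counts = sample_counts(truth, 5000, 0.1, seed=9)
        res = overall_spatial_test(counts, "g1", truth.basis)
        assert res.p_value < 1e-6
        assert res.df == truth.basis.L

    def test_flat_truth_mostly_non_significant(self):
        coords, W = gen_landscape(800, 1, "uniform", seed=10)
        truth = gen_truth_surface(coords, W, k=5, coef_scale=0.0, seed=11)
        ps = []
        for rep in range(10):
            counts = sample_counts(truth, 800, 0.1, seed=100 + rep)
            ps.append(overall_spatial_test(counts, "g1", truth.basis).p_value)
        assert np.mean(np.array(ps) < 0.05) <= 0.3

    def test_statistic_floored_at_zero(self):
        from asemap.inference import _lrt

        stat, p, w = _lrt(10.0, 10.5, 4)
        assert stat == 0.0 and p == 1.0 and w


class TestClassification:
    def _results_frame(self):
        rows = [
            # gene A: overall maternal + overall spatial
            dict(gene="A", category="overall_bias", cell_type=None, p=1e-5,
                 q=1e-4, direction="maternal", p_hat=0.8),
            dict(gene="A", category="overall_spatial", cell_type=None, p=1e-6,
                 q=1e-5, direction="none", p_hat=np.nan),
            # gene B: nothing significant
            dict(gene="B", category="overall_bias", cell_type=None, p=0.5,
                 q=0.8, direction="none", p_hat=0.52),
            # gene C: significant but direction none (p_hat in dead zone)
            dict(gene="C", category="overall_bias", cell_type=None, p=1e-4,
                 q=1e-3, direction="none", p_hat=0.55),
            # gene D: within-ct paternal
            dict(gene="D", category="within_ct_bias", cell_type="ct1", p=1e-5,
                 q=1e-4, direction="paternal", p_hat=0.2),
        ]
        return pd.DataFrame(rows)

    def test_multi_membership_and_exclusivity(self):
        summary = classify_genes(self._results_frame(), q_cutoff=0.01)
        s = dict(zip(summary["category"], summary["n_genes"]))
        assert s["overall maternal bias"] == 1
        assert s["overall spatial pattern"] == 1
        assert s["within cell type paternal bias"] == 1
        # B (nothing) and C (no direction) fall in the exclusive null row
        assert s["no significant ASE"] == 2
        assert set(summary["category"]) == set(SUMMARY_ROWS)

    def test_chromosome_split(self):
        summary = classify_genes(
            self._results_frame(), q_cutoff=0.01,
            chromosome_map={"A": "X", "B": "2", "C": "3", "D": "7"},
        )
        row = summary[summary["category"] == "overall maternal bias"].iloc[0]
        assert row["n_x"] == 1 and row["n_autosomal"] == 0


class TestBattery:
    def test_direction_rule_never_violated(self):
        rng = np.random.default_rng(12)
        S, G = 600, 8
        coords = rng.uniform(size=(S, 2))
        N = rng.integers(0, 6, size=(S, G))
        probs = rng.uniform(0.3, 0.9, G)
        Y = rng.binomial(N, probs[None, :])
        counts = SpatialAllelicCounts(
            spot_ids=[f"s{i}" for i in range(S)],
            gene_ids=[f"g{j}" for j in range(G)],
            Y=sparse.csr_matrix(Y), N=sparse.csr_matrix(N), coords=coords,
        )
        df = run_test_battery(counts, categories=("overall_bias",), min_nonzero=50)
        assert len(df) == G
        mat = df[df["direction"] == "maternal"]
        pat = df[df["direction"] == "paternal"]
        assert (mat["p_hat"] > 0.6).all() and (mat["q"] < 0.01).all()
        assert (pat["p_hat"] < 0.4).all() and (pat["q"] < 0.01).all()
        none_sig = df[(df["q"] < 0.01) & (df["direction"] == "none")]
        assert ((none_sig["p_hat"] >= 0.4) & (none_sig["p_hat"] <= 0.6)).all()

    def test_unknown_category_rejected(self, small_counts):
        with pytest.raises(ValueError, match="unknown categories"):
            run_test_battery(small_counts, categories=("nonsense",))
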