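"""Correlation powering, the scale-free diagnostic and the edge cut-off."""

import numpy as np
import pandas as pd
import pytest

from coexnet.network import (
    NetworkConfig,
    pairwise_correlation,
    scale_free_fit,
    soft_power_adjacency,
    threshold_network,
)


def _expr(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=genes, columns=[f"s{j}" for j in range(mat.shape[1])])


class TestCorrelation:
    def test_unit_diagonal_and_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r = pairwise_correlation(_expr([x, -x, 2 * x + 1]))
        assert np.allclose(np.diag(r), 1.0)
        assert r.iloc[0, 1] == pytest.approx(-1.0)
        assert r.iloc[0, 2] == pytest.approx(1.0)

    def test_matches_elementwise_covariance_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(5, 12))
        r = pairwise_correlation(_expr(mat))
        for i in range(5):
            for j in range(5):
                xi, xj = mat[i] - mat[i].mean(), mat[j] - mat[j].mean()
                expect = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert r.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self):
        mat = np.vstack([np.arange(6.0), np.full(6, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = pairwise_correlation(_expr(mat))
        assert list(r.index) == ["g0"]


class TestSoftPower:
    def test_published_constants(self):
        # |r| = 0.8 at the recommended beta = 7 gives weight 0.8^7
        r = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=["a", "b"], columns=["a", "b"])
        a = soft_power_adjacency(r, NetworkConfig(beta=7))
        assert a.iloc[0, 1] == pytest.approx(0.8**7)
        assert a.iloc[0, 1] == pytest.approx(0.2097152)

    def test_fixed_points_and_monotonicity(self):
        vals = np.array([[1.0, 0.0, 0.3], [0.0, 1.0, 0.6], [0.3, 0.6, 1.0]])
        r = pd.DataFrame(vals, index=list("abc"), columns=list("abc"))
        for beta in (1, 3, 7):
            a = soft_power_adjacency(r, NetworkConfig(beta=beta))
            assert a.loc["a", "b"] == 0.0
            assert a.loc["a", "c"] < a.loc["b", "c"]
        assert np.allclose(np.diag(soft_power_adjacency(r, NetworkConfig()).to_numpy()), 0.0)


class TestScaleFree:
    def test_planted_power_law_fits_perfectly(self):
        # 2^(9-j) nodes of connectivity 4^j: log p(k) is exactly linear in
        # log k (slope -1/2), one distinct k per logarithmic bin
        k = np.concatenate([np.full(2 ** (9 - j), 4.0**j) for j in range(10)])
        r2 = scale_free_fit(pd.DataFrame(np.diag(k)))
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_homogeneous_network_scores_below_scale_free(self):
        rng = np.random.default_rng(2)
        n = 400
        er = rng.uniform(0.4, 0.6, size=(n, n))
        er = (er + er.T) / 2
        np.fill_diagonal(er, 0)
        k_sf = (1.0 - rng.uniform(size=n)) ** (-1 / 1.5)
        r2_er = scale_free_fit(pd.DataFrame(er))
        r2_sf = scale_free_fit(pd.DataFrame(np.diag(k_sf)))
        assert np.isnan(r2_er) or r2_er < r2_sf

    def test_invariant_to_node_relabelling(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(50, 50))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        perm = rng.permutation(50)
        assert scale_free_fit(pd.DataFrame(a)) == pytest.approx(
            scale_free_fit(pd.DataFrame(a[np.ix_(perm, perm)])), abs=1e-12
        )

    def test_degenerate_equal_connectivity_is_nan(self):
        a = np.ones((4, 4)) - np.eye(4)
        assert np.isnan(scale_free_fit(pd.DataFrame(a)))


class TestThreshold:
    def test_boundary_inclusive_at_cutoff(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.80
        vals[0, 2] = vals[2, 0] = 0.79
        vals[1, 2] = vals[2, 1] = -0.85
        net = threshold_network(pd.DataFrame(vals, index=list("abc"), columns=list("abc")))
        pairs = set(zip(net.edges["gene_a"], net.edges["gene_b"]))
        assert ("a", "b") in pairs          # |r| = 0.80 retained (inclusive)
        assert ("a", "c") not in pairs      # 0.79 dropped
        assert ("b", "c") in pairs          # unsigned: |-0.85| kept

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(6, 20))
        mat[1] = mat[0] + 0.1 * rng.normal(size=20)
        mat[3] = -mat[2] + 0.2 * rng.normal(size=20)
        expr = _expr(mat)
        r = pairwise_correlation(expr)
        net = threshold_network(r, NetworkConfig(beta=7, r_cutoff=0.8))
        expected = set()
        for i in range(6):
            for j in range(i + 1, 6):
                if abs(r.iloc[i, j]) >= 0.8:
                    expected.add((f"g{i}", f"g{j}"))
        assert set(zip(net.edges["gene_a"], net.edges["gene_b"])) == expected
        for _, row in net.edges.iterrows():
            assert row["weight"] == pytest.approx(abs(row["r"]) ** 7, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(8, 15))
        mat[4] = mat[2] + 0.05 * rng.normal(size=15)
        expr = _expr(mat)
        net1 = threshold_network(pairwise_correlation(expr))
        perm = expr.iloc[rng.permutation(8)]
        net2 = threshold_network(pairwise_correlation(perm))
        e1 = set(zip(net1.edges["gene_a"], net1.edges["gene_b"]))
        e2 = set(zip(net2.edges["gene_a"], net2.edges["gene_b"]))
        assert e1 == e2

    def test_edge_weights_recompute_from_expression(self, planted_run):
        from coexnet.preprocess import filter_low_expression, log_cpm, tmm_factors

        _, cm, _ = planted_run
        filt = filter_low_expression(cm)
        expr = log_cpm(filt, tmm_factors(cm))
        net = threshold_network(pairwise_correlation(expr))
        rng = np.random.default_rng(6)
        rows = net.edges.iloc[rng.choice(len(net.edges), 100, replace=False)]
        mat = expr.log2_cpm
        for _, row in rows.iterrows():
            x, y = mat.loc[row["gene_a"]], mat.loc[row["gene_b"]]
            r = np.corrcoef(x, y)[0, 1]
            assert row["weight"] == pytest.approx(abs(r) ** 7, abs=1e-9)

    def test_mostly_intra_module_edges_on_planted_data(self, planted_run):
        from coexnet.preprocess import filter_low_expression, log_cpm, tmm_factors

        _, cm, truth = planted_run
        filt = filter_low_expression(cm)
        expr = log_cpm(filt, tmm_factors(cm))
        net = threshold_network(pairwise_correlation(expr))
        intra = sum(
            truth.module_of[a] is not None and truth.module_of[a] == truth.module_of[b]
            for a, b in zip(net.edges["gene_a"], net.edges["gene_b"])
        )
        assert intra / len(net.edges) >= 0.95
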