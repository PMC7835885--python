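"""Spearman matrix, significance, network construction, threshold scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import physnet as pn
from conftest import make_table


def brute_spearman(x, y):
    """Rank explicitly, then covariance over deviation product."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.cov(rx, ry, ddof=1)[0, 1] / (np.std(rx, ddof=1) * np.std(ry, ddof=1))


class TestSpearmanMatrix:
    def test_monotone_sequences(self):
        t = make_table(np.column_stack([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]]))
        assert pn.spearman_matrix(t).rho.iloc[0, 1] == pytest.approx(1.0)
        t = make_table(np.column_stack([[1, 2, 3], [3, 2, 1]]))
        assert pn.spearman_matrix(t).rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_rank_difference_formula(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 2
        t = make_table(np.column_stack([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert pn.spearman_matrix(t).rho.iloc[0, 1] == pytest.approx(0.8)

    def test_matches_brute_force_on_random_tables(self):
        """Oracle equivalence to 1e-12 on random 10 x 6 tables."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            arr = rng.random((10, 6))
            res = pn.spearman_matrix(make_table(arr))
            for i in range(6):
                for j in range(i + 1, 6):
                    assert res.rho.iloc[i, j] == pytest.approx(
                        brute_spearman(arr[:, i], arr[:, j]), abs=1e-12
                    )

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 5, size=(30, 4)).astype(float)  # heavy ties
        res = pn.spearman_matrix(make_table(arr))
        ref = stats.spearmanr(arr)
        np.testing.assert_allclose(res.rho.to_numpy(), ref.statistic, atol=1e-12)
        np.testing.assert_allclose(res.p.to_numpy(), ref.pvalue, atol=1e-12)

    def test_pairwise_complete_with_missing_cells(self):
        arr = np.column_stack([np.arange(20.0), np.arange(20.0) ** 2, np.arange(20.0)[::-1]])
        arr[0, 0] = np.nan
        arr[5, 1] = np.nan
        res = pn.spearman_matrix(make_table(arr))
        assert res.n_obs.iloc[0, 1] == 18
        assert res.n_obs.iloc[0, 2] == 19
        assert res.rho.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_column_marked_untestable_not_nan_propagation(self):
        arr = np.column_stack([np.ones(10), np.arange(10.0)])
        res = pn.spearman_matrix(make_table(arr))
        assert np.isnan(res.rho.iloc[0, 1])
        assert res.p.iloc[0, 1] == 1.0
        assert res.rho.iloc[1, 1] == 1.0

    def test_too_few_pairwise_observations_gives_p_one(self):
        arr = np.full((6, 2), np.nan)
        arr[:3, 0] = [1, 2, 3]
        arr[:3, 1] = [1, 2, 3]
        res = pn.spearman_matrix(make_table(arr))
        assert res.p.iloc[0, 1] == 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((12, 5))
        res = pn.spearman_matrix(make_table(arr))
        r = res.rho.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=0)
        assert (np.abs(r[~np.isnan(r)]) <= 1 + 1e-12).all()
        assert ((res.p.to_numpy() >= 0) & (res.p.to_numpy() <= 1)).all()


class TestPValue:
    def test_conventions(self):
        assert pn.spearman_pvalue(0.0, 100) == pytest.approx(1.0)
        assert pn.spearman_pvalue(1.0, 10) == 0.0
        assert pn.spearman_pvalue(0.5, 3) == 1.0

    def test_t_distribution_oracle(self):
        # rho=0.8, n=4 -> t = 0.8*sqrt(2/0.36), df=2
        t = 0.8 * np.sqrt(2 / 0.36)
        expected = 2 * stats.t.sf(t, df=2)
        assert pn.spearman_pvalue(0.8, 4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2, abs=0.01)


class TestBuildNetwork:
    def _corr(self, p01, p02, p12):
        idx = pd.Index(["a", "b", "c"])
        rho = pd.DataFrame(np.full((3, 3), 0.5), index=idx, columns=idx)
        np.fill_diagonal(rho.values, 1.0)
        p = pd.DataFrame(
            [[0, p01, p02], [p01, 0, p12], [p02, p12, 0]], index=idx, columns=idx, dtype=float
        )
        n = pd.DataFrame(np.full((3, 3), 50), index=idx, columns=idx)
        return pn.CorrelationResult(rho=rho, p=p, n_obs=n)

    def test_alpha_one_gives_complete_graph(self):
        net = pn.build_network(self._corr(0.0005, 0.05, 0.5), 1.0)
        assert net.number_of_edges() == 3

    def test_edge_counting_at_strict_threshold(self):
        net = pn.build_network(self._corr(0.0005, 0.05, 0.5), 0.001)
        assert net.number_of_edges() == 1
        assert net.graph.has_edge("a", "b")

    def test_tiny_alpha_keeps_isolates_as_nodes(self):
        net = pn.build_network(self._corr(0.0005, 0.05, 0.5), 1e-12)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 3

    def test_edge_attributes_hold_weight_sign_and_p(self):
        net = pn.build_network(self._corr(0.0005, 0.05, 0.5), 0.001)
        d = net.graph["a"]["b"]
        assert d["weight"] == pytest.approx(0.25)
        assert d["rho"] == pytest.approx(0.5)
        assert d["p"] == pytest.approx(0.0005)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            pn.build_network(self._corr(0.1, 0.1, 0.1), 0.0)


class TestScan:
    def _random_corr(self, seed=0, n=100, p=15):
        rng = np.random.default_rng(seed)
        arr = rng.standard_normal((n, p))
        arr[:, 1:5] += arr[:, [0]]  # correlated group
        return pn.spearman_matrix(make_table(arr))

    def test_edge_count_monotone_along_grid(self):
        scan = pn.threshold_scan(self._random_corr(), seed=0, B=0)
        edges = scan.records.sort_values("alpha", ascending=False)["edges"]
        assert (edges.diff().dropna() <= 0).all()

    def test_grid_of_one_gives_fully_connected_entry(self):
        scan = pn.threshold_scan(self._random_corr(), grid=[1.0], seed=0, B=0)
        rec = scan.records.iloc[0]
        assert rec["density"] == pytest.approx(1.0)

    def test_removed_links_are_weakest(self):
        """Tightening the threshold preferentially removes the weakest links."""
        corr = self._random_corr(seed=3)
        n1 = pn.build_network(corr, 0.05)
        n2 = pn.build_network(corr, 0.001)
        kept = {frozenset(e) for e in n2.edges}
        removed_w = [d["weight"] for u, v, d in n1.graph.edges(data=True) if frozenset((u, v)) not in kept]
        kept_w = [d["weight"] for u, v, d in n1.graph.edges(data=True) if frozenset((u, v)) in kept]
        assert removed_w and kept_w
        assert np.mean(removed_w) <= np.mean(kept_w)

    def test_planted_modularity_higher_at_stricter_threshold(self, planted_spec):
        table, _ = pn.generate_cohort(planted_spec(0))
        corr = pn.spearman_matrix(table)
        scan = pn.threshold_scan(corr, grid=[0.05, 0.001], seed=0, B=0)
        rec = scan.records.set_index("alpha")
        assert rec.loc[0.001, "modularity_louvain"] >= rec.loc[0.05, "modularity_louvain"]

    def test_select_threshold_rule(self):
        records = pd.DataFrame(
            {"alpha": [0.05, 0.01, 0.001, 0.0001], "connectedness": [1, 0.98, 0.96, 0.7]}
        )
        scan = pn.ThresholdScanResult(alphas=[0.05, 0.01, 0.001, 0.0001], records=records)
        assert pn.select_threshold(scan, 0.95) == 0.001
        assert pn.select_threshold(scan, 0.0) == 0.0001
        with pytest.warns(UserWarning, match="no threshold"):
            assert pn.select_threshold(scan, 1.1) == 0.05

    def test_type_one_error_calibration_on_null_cohorts(self):
        """Fraction of edges at alpha=0.01 on independent data is ~1%."""
        fracs = []
        n_seeds, p = 50, 30
        for seed in range(n_seeds):
            spec = pn.CohortSpec(
                n_subjects=150, blocks=[pn.BlockSpec("x", p, 0.0)], seed=seed
            )
            table, _ = pn.generate_cohort(spec)
            pv = pn.spearman_matrix(table).p.to_numpy()
            iu = np.triu_indices(p, k=1)
            fracs.append((pv[iu] < 0.01).mean())
        n_pairs = n_seeds * p * (p - 1) // 2
        se = np.sqrt(0.01 * 0.99 / n_pairs)
        assert abs(np.mean(fracs) - 0.01) < 3 * se
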