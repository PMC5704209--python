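"""Clustering, histogram, correlation and power-law statistics."""

import math

import networkx as nx
import numpy as np
import pytest

from mircoreg import (
    ParameterError,
    clustering_exact,
    clustering_sampled,
    degree_clustering_correlation,
    degree_histogram,
    fit_power_law,
    rank_by_count,
    sample_power_law_degrees,
    sqrt_normality_diagnostic,
)
from mircoreg.network import BipartiteTargetMap, CoRegulationNetwork

from conftest import brute_force_clustering


def _from_nx(graph) -> CoRegulationNetwork:
    return CoRegulationNetwork.from_edges(
        [str(n) for n in graph.nodes], [(str(a), str(b)) for a, b in graph.edges]
    )


class TestClusteringExact:
    def test_triangle_all_one(self):
        net = CoRegulationNetwork.from_edges(["a", "b", "c"], [("a", "b"), ("a", "c"), ("b", "c")])
        res = clustering_exact(net)
        assert (res.table["c"] == 1.0).all()

    def test_star_center_zero_leaves_undefined(self):
        net = CoRegulationNetwork.from_edges(
            ["hub", "l1", "l2", "l3", "l4"], [("hub", f"l{i}") for i in range(1, 5)]
        )
        res = clustering_exact(net)
        row = res.table.set_index("gene")
        assert row.loc["hub", "c"] == 0.0 and row.loc["hub", "k"] == 4
        assert res.table.set_index("gene").loc[["l1", "l2", "l3", "l4"], "c"].isna().all()

    def test_complete_graph_and_tree_limits(self):
        comp = _from_nx(nx.complete_graph(8))
        assert (clustering_exact(comp).table["c"] == 1.0).all()
        tree = _from_nx(nx.random_labeled_tree(20, seed=4))
        res = clustering_exact(tree)
        assert (res.table.loc[res.defined, "c"] == 0.0).all()

    def test_matches_enumeration_and_networkx_on_random_graphs(self):
        """Exact C_i equals the all-pairs oracle and networkx on 30-node graphs."""
        for seed in range(6):
            g = nx.gnp_random_graph(30, 0.2, seed=seed)
            net = _from_nx(g)
            res = clustering_exact(net)
            oracle = brute_force_clustering(net)
            nx_c = nx.clustering(nx.relabel_nodes(g, str))
            for _, row in res.table.iterrows():
                k, n_i, c = oracle[row["gene"]]
                assert row["k"] == k and row["n_i"] == n_i
                if k >= 2:
                    assert row["c"] == pytest.approx(c) == pytest.approx(nx_c[row["gene"]])
                else:
                    assert math.isnan(row["c"])

    def test_identity_c_times_pairs_is_integer_edge_count(self):
        g = nx.gnp_random_graph(40, 0.25, seed=9)
        net = _from_nx(g)
        res = clustering_exact(net)
        sub = res.table[res.defined]
        recon = sub["c"] * sub["k"] * (sub["k"] - 1) / 2
        assert np.allclose(recon, sub["n_i"])
        assert (np.abs(recon - np.round(recon)) < 1e-9).all()


class TestClusteringSampled:
    def _hub_graph(self, degree=200, p=0.3, seed=0):
        rng = np.random.default_rng(seed)
        leaves = [f"v{i:03d}" for i in range(degree)]
        edges = [("hub", v) for v in leaves]
        for i in range(degree):
            for j in range(i + 1, degree):
                if rng.random() < p:
                    edges.append((leaves[i], leaves[j]))
        return CoRegulationNetwork.from_edges(["hub"] + leaves, edges)

    def test_exhaustion_equals_exact(self):
        net = self._hub_graph(degree=40, seed=1)
        exact = clustering_exact(net).as_mapping()
        sampled = clustering_sampled(net, pairs_per_node=40 * 39 // 2, seed=5).as_mapping()
        for g in exact:
            assert sampled[g] == pytest.approx(exact[g]) or (
                math.isnan(exact[g]) and math.isnan(sampled[g])
            )

    def test_unbiased_on_hub_within_two_se(self):
        """Mean sampled hub-C over 50 seeds within 2 SEs of the exact value."""
        net = self._hub_graph(degree=200, p=0.3, seed=2)
        exact = clustering_exact(net).as_mapping()["hub"]
        budget = 2000
        estimates = [
            clustering_sampled(net, pairs_per_node=budget, seed=s).as_mapping()["hub"]
            for s in range(50)
        ]
        se_one = math.sqrt(exact * (1 - exact) / budget)
        se_mean = se_one / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - exact) <= 2 * se_mean

    def test_same_seed_identical(self):
        net = self._hub_graph(degree=80, seed=3)
        a = clustering_sampled(net, 100, seed=11).table
        b = clustering_sampled(net, 100, seed=11).table
        assert a.equals(b)


class TestHistograms:
    def test_linear_unit_bins(self):
        dist = degree_histogram([1, 1, 2, 3], scale="linear", bin_width_or_count=1)
        assert dist.values == {1: 2, 2: 1, 3: 1}
        assert dist.bin_counts.sum() == 4

    def test_count_conservation_on_synthetic_values(self):
        draws = sample_power_law_degrees(5000, 2.2, 1, 500, seed=8)
        for scale in ("linear", "sqrt", "loglog"):
            dist = degree_histogram(draws, scale=scale)
            assert dist.bin_counts.sum() == len(draws)
            assert (np.diff(dist.bin_edges) > 0).all()

    def test_loglog_binned_slope_recovers_exponent(self):
        """Log-log regression slope within 0.3 of -2.5 on a big sample."""
        draws = sample_power_law_degrees(200_000, 2.5, 1, 1000, seed=21)
        fit = fit_power_law(draws, method="loglog-regression")
        assert fit.alpha == pytest.approx(2.5, abs=0.3)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            degree_histogram([], scale="linear")


class TestSqrtDiagnostic:
    def test_sqrt_reduces_skew_of_squared_normals(self):
        """Values built as squares of normals: sqrt transform symmetrises."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = np.abs(rng.normal(50, 12, size=4000))
            values = np.round(base**2).astype(int)
            diag = sqrt_normality_diagnostic(values)
            if abs(diag.skew_sqrt) < abs(diag.skew_raw):
                wins += 1
        assert wins == 20

    def test_symmetric_input_zero_skew(self):
        diag = sqrt_normality_diagnostic([1, 2, 3])
        assert diag.skew_raw == pytest.approx(0.0)

    def test_constant_input_flagged(self):
        assert sqrt_normality_diagnostic([5, 5, 5]).undefined


class TestDegreeClusteringCorrelation:
    def test_perfect_negative_linear_case(self):
        import pandas as pd
        from mircoreg.netstats import ClusteringResult

        k = np.array([4, 9, 25])
        c = 1 - 0.1 * np.sqrt(k)
        table = pd.DataFrame(
            {"gene": ["a", "b", "c"], "k": k, "n_i": 0, "c": c, "method": "exact"}
        )
        res = degree_clustering_correlation(ClusteringResult(table))
        assert res.r_sqrt == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-0.1)

    def test_constant_clustering_flagged(self):
        import pandas as pd
        from mircoreg.netstats import ClusteringResult

        table = pd.DataFrame(
            {"gene": list("abcd"), "k": [2, 3, 4, 5], "n_i": 1, "c": 0.5, "method": "exact"}
        )
        assert degree_clustering_correlation(ClusteringResult(table)).undefined

    def test_too_few_defined_points_error(self):
        net = CoRegulationNetwork.from_edges(["a", "b"], [("a", "b")])
        with pytest.raises(ParameterError):
            degree_clustering_correlation(clustering_exact(net))

    def test_sign_matches_independent_recomputation(self):
        g = nx.watts_strogatz_graph(300, 10, 0.2, seed=12)
        net = _from_nx(g)
        res = degree_clustering_correlation(clustering_exact(net))
        # independent recomputation: numpy corrcoef on networkx clustering
        nxg = nx.relabel_nodes(g, str)
        cc = nx.clustering(nxg)
        nodes = [n for n in nxg.nodes if nxg.degree[n] >= 2]
        r = np.corrcoef(
            [math.sqrt(nxg.degree[n]) for n in nodes], [cc[n] for n in nodes]
        )[0, 1]
        assert np.sign(res.r_sqrt) == np.sign(r)
        assert res.r_sqrt == pytest.approx(r, abs=1e-9)


class TestPowerLawFit:
    def test_mle_recovers_alpha_on_large_sample(self):
        """n=1e5 at alpha=2.5: estimate lands in [2.45, 2.55]."""
        draws = sample_power_law_degrees(100_000, 2.5, 1, 1000, seed=33)
        fit = fit_power_law(draws, method="mle", k_min_fit=1, k_max_fit=1000)
        assert 2.45 <= fit.alpha <= 2.55
        assert fit.stderr_alpha < 0.02

    def test_geometric_tail_fits_worse_than_power_law(self):
        """Paired KS comparison over 20 seeds: exponential tails lose."""
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 4000
            pl = sample_power_law_degrees(n, 2.5, 1, 1000, seed=seed)
            geo = rng.geometric(p=0.3, size=n)
            f_pl = fit_power_law(pl, k_min_fit=1, k_max_fit=1000)
            f_geo = fit_power_law(geo, k_min_fit=1)
            if f_geo.gof > f_pl.gof:
                worse += 1
        assert worse == 20

    def test_auto_kmin_finds_clean_tail(self):
        """Noise below K=5, power law above: auto cutoff lands near 5."""
        rng = np.random.default_rng(3)
        body = rng.integers(1, 5, size=3000)
        tail = sample_power_law_degrees(3000, 2.2, 5, 2000, seed=3)
        fit = fit_power_law(np.concatenate([body, tail]), k_min_fit="auto")
        assert 4 <= fit.k_min_fit <= 8
        assert fit.alpha == pytest.approx(2.2, abs=0.25)

    def test_constant_values_error(self):
        with pytest.raises(ParameterError):
            fit_power_law([7] * 100, k_min_fit=1)

    def test_summary_mentions_key_fields(self):
        draws = sample_power_law_degrees(2000, 2.0, 1, 100, seed=0)
        text = fit_power_law(draws, k_min_fit=1).summary()
        assert "alpha" in text and "KS distance" in text


class TestRankByCount:
    def _bimap(self, gene_counts, mirna_counts=None):
        mirna_counts = mirna_counts or {"m1": 1}
        return BipartiteTargetMap(
            mirna_to_genes={m: frozenset() for m in mirna_counts},
            gene_to_mirnas={g: frozenset() for g in gene_counts},
            gene_site_counts=gene_counts,
            mirna_target_counts=mirna_counts,
        )

    def test_tie_break_is_lexicographic(self):
        rank = rank_by_count(self._bimap({"a": 3, "b": 1, "c": 3}), axis="gene", top_n=2)
        assert rank.top(2) == ["a", "c"]
        assert rank.is_in_top("a", 2) and not rank.is_in_top("b", 2)

    def test_top_n_beyond_population_returns_all(self):
        rank = rank_by_count(self._bimap({"a": 3, "b": 1}), axis="gene", top_n=10)
        assert len(rank.table) == 2

    def test_planted_genes_overrepresented_in_top_decile(self):
        """Across 20 seeds, planted genes exceed their base rate in the top 10%."""
        from mircoreg import SyntheticConfig, build_bipartite, generate_bipartite_table

        enriched = 0
        for seed in range(20):
            cfg = SyntheticConfig(n_genes=500, n_mirnas=120, seed=seed)
            table = generate_bipartite_table(cfg)
            bimap = build_bipartite(table)
            rank = rank_by_count(bimap, axis="gene")
            top = set(rank.top(len(rank.table) // 10))
            planted = set(table.metadata["planted_genes"]) & set(bimap.gene_to_mirnas)
            frac_top = len(top & planted) / len(top)
            frac_all = len(planted) / bimap.n_genes
            if frac_top > frac_all:
                enriched += 1
        assert enriched >= 18
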