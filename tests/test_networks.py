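"""Co-occurrence network construction and topology metrics."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from airway_recovery import networks as nw


def graph_from_edges(edges, nodes=None, r=1.0):
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, r=r, sign=1 if r > 0 else -1, abs_r=abs(r),
                   dissim=float(np.sqrt(2 * (1 - r))) if r < 1 else 1.0)
    return g


class TestCoreAsvFilter:
    @pytest.fixture()
    def stratum(self):
        counts = pd.DataFrame({
            "keep": [1, 1, 1, 0, 0, 0], "half": [1, 0, 1, 0, 1, 0],
            "rare": [1, 0, 0, 0, 0, 0]},
            index=[f"s{i}" for i in range(6)])
        counts["keep"] = [1, 1, 1, 1, 0, 0]
        meta = pd.DataFrame({"subject_id": [f"p{i}" for i in range(6)],
                             "site": "BAL", "group": "AS"}, index=counts.index)
        return counts, meta

    def test_inclusive_half_boundary(self, stratum):
        counts, meta = stratum
        out = nw.core_asv_filter(counts, meta, "AS", "BAL", threshold=0.5)
        assert "half" in out.columns and "rare" not in out.columns

    def test_raising_threshold_never_adds(self, stratum):
        counts, meta = stratum
        low = set(nw.core_asv_filter(counts, meta, "AS", "BAL", 0.3).columns)
        high = set(nw.core_asv_filter(counts, meta, "AS", "BAL", 0.7).columns)
        assert high <= low

    def test_empty_stratum_error(self, stratum):
        counts, meta = stratum
        with pytest.raises(ValueError):
            nw.core_asv_filter(counts, meta, "NS", "BAL")


class TestBuildNetwork:
    def test_proportional_asvs_get_unit_edge(self, rng):
        base = rng.lognormal(size=20) * 100
        vals = pd.DataFrame({"a": base, "b": 3 * base,
                             "c": rng.lognormal(size=20)})
        g = nw.build_network(vals, r_threshold=0.3)
        assert g.has_edge("a", "b")
        # log(x+1) makes proportionality only asymptotically exact
        assert g["a"]["b"]["r"] == pytest.approx(1.0, abs=1e-3)

    def test_subthreshold_pair_has_no_edge(self, rng):
        n = 2000  # large n so sample correlation is near its population value
        x = rng.standard_normal(n)
        y = 0.25 * x + np.sqrt(1 - 0.25**2) * rng.standard_normal(n)
        vals = pd.DataFrame({"a": 1000 * np.exp(x), "b": 1000 * np.exp(y),
                             "c": 1000 * np.exp(rng.standard_normal(n))})
        g = nw.build_network(vals, r_threshold=0.3)
        assert not g.has_edge("a", "b")

    def test_too_few_samples_rejected(self):
        vals = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(ValueError, match="samples"):
            nw.build_network(vals)

    def test_constant_asv_is_isolated(self, rng):
        vals = pd.DataFrame({"a": rng.lognormal(size=10),
                             "b": rng.lognormal(size=10),
                             "const": np.full(10, 5.0)})
        g = nw.build_network(vals, r_threshold=0.1)
        assert g.degree("const") == 0


class TestTopology:
    def test_complete_graph_closed_form(self):
        k5 = graph_from_edges(combinations(range(5), 2))
        rec = nw.topology(k5, seed=0)
        assert rec.edge_density == 1.0
        assert rec.clustering_coefficient == 1.0
        assert rec.pep == 100.0
        assert rec.n_modules == 1
        assert rec.robustness == 1.0

    def test_path_graph_average_path_length(self):
        p4 = graph_from_edges([(0, 1), (1, 2), (2, 3)])
        rec = nw.topology(p4, seed=0)
        assert rec.avg_path_length == pytest.approx((1 * 3 + 2 * 2 + 3 * 1) / 6)

    def test_two_cliques_modularity_is_exhaustive_optimum(self):
        from airway_recovery.experiments import exhaustive_modularity
        g = graph_from_edges(list(combinations(range(4), 2))
                             + list(combinations(range(4, 8), 2)))
        rec = nw.topology(g, seed=0)
        assert rec.modularity == pytest.approx(0.5)
        assert rec.modularity == pytest.approx(exhaustive_modularity(g))
        assert rec.n_modules == 2

    def test_edgeless_graph_degenerate_record(self):
        g = graph_from_edges([], nodes=range(4))
        rec = nw.topology(g, seed=0)
        assert rec.edge_density == 0.0 and rec.pep == 0.0
        assert np.isnan(rec.avg_path_length)
        assert rec.n_modules == 4

    def test_metrics_invariant_to_relabelling(self, rng):
        g = nx.gnp_random_graph(8, 0.5, seed=4)
        for a, b in g.edges:
            g[a][b].update(r=1.0, sign=1, abs_r=1.0, dissim=1.0)
        mapping = dict(zip(g.nodes, rng.permutation([f"n{i}" for i in range(8)])))
        h = nx.relabel_nodes(g, mapping)
        ra, rb = nw.topology(g, seed=0), nw.topology(h, seed=0)
        assert ra.to_dict() == pytest.approx(rb.to_dict(), nan_ok=True)


class TestRobustness:
    def test_complete_graph_exactly_one(self):
        for n in (2, 5, 10):
            g = graph_from_edges(combinations(range(n), 2))
            assert nw.robustness(g, 0.5, n_rep=20, seed=0) == 1.0

    def test_edgeless_graph(self):
        g = graph_from_edges([], nodes=range(6))
        # 3 survivors, all isolated: largest component 1 of 3
        assert nw.robustness(g, 0.5, n_rep=10, seed=0) == pytest.approx(1 / 3)

    def test_star_less_robust_than_complete(self):
        star = graph_from_edges([(0, i) for i in range(1, 10)])
        k10 = graph_from_edges(combinations(range(10), 2))
        assert (nw.robustness(star, 0.5, n_rep=200, seed=1)
                < nw.robustness(k10, 0.5, n_rep=200, seed=1))

    def test_invalid_fraction(self):
        g = graph_from_edges([(0, 1)])
        with pytest.raises(ValueError):
            nw.robustness(g, 1.0)

    def test_seeded_determinism(self):
        g = graph_from_edges([(0, 1), (1, 2), (3, 4)], nodes=range(6))
        assert nw.robustness(g, 0.5, seed=9) == nw.robustness(g, 0.5, seed=9)


class TestDetectHubs:
    def test_star_center_unique_hub(self):
        star = graph_from_edges([(0, i) for i in range(1, 20)])  # 20 nodes
        assert nw.detect_hubs(star, quantile=0.95) == {0}

    def test_ring_all_tie(self):
        ring = graph_from_edges([(i, (i + 1) % 8) for i in range(8)])
        assert nw.detect_hubs(ring, quantile=0.95) == set(range(8))

    def test_empty_graph(self):
        assert nw.detect_hubs(nx.Graph()) == set()


class TestCompareNetworks:
    def test_identical_networks(self):
        g = graph_from_edges(combinations(range(5), 2))
        rec = nw.topology(g, seed=0)
        metrics, jac = nw.compare_networks({"a": rec, "b": rec},
                                           {"a": {1, 2}, "b": {1, 2}})
        assert (metrics["a"] == metrics["b"]).all()
        assert jac.loc["a", "b"] == 1.0

    def test_disjoint_hub_sets(self):
        g = graph_from_edges(combinations(range(5), 2))
        rec = nw.topology(g, seed=0)
        _, jac = nw.compare_networks({"a": rec, "b": rec},
                                     {"a": {1}, "b": {2}})
        assert jac.loc["a", "b"] == 0.0

    def test_density_delta_consistent_with_topology(self):
        k10 = graph_from_edges(combinations(range(10), 2))
        p10 = graph_from_edges([(i, i + 1) for i in range(9)])
        metrics, _ = nw.compare_networks(
            {"K10": nw.topology(k10, seed=0), "P10": nw.topology(p10, seed=0)},
            {"K10": set(), "P10": set()})
        assert metrics.loc["edge_density", "K10"] == 1.0
        assert metrics.loc["edge_density", "P10"] == pytest.approx(9 / 45)
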