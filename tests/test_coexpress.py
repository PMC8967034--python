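from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from protscape.coexpress import (
    assign_module_phenotype,
    build_network,
    clr_pearson,
    extract_modules,
    modules_to_table,
    sparcc,
    suggest_pathways,
)
from protscape.io_formats import SampleManifest


def _null_counts(rng, m=20, n=200, depth=5000, sigma=1.0, block=None, rho=0.8):
    cov = np.eye(m)
    if block:
        cov[:block, :block] = rho
        np.fill_diagonal(cov, 1.0)
    logs = rng.multivariate_normal(np.zeros(m), cov * sigma ** 2, size=n).T
    frac = np.exp(logs)
    frac /= frac.sum(axis=0, keepdims=True)
    return np.vstack([rng.multinomial(depth, frac[:, j]) for j in range(n)]).T


class TestSparcc:
    def test_proportional_rows_give_rho_one(self):
        # y + pc = 3 (x + pc): the log-ratio is constant, so t_ij = 0
        x = np.array([10.0, 4.0, 25.0, 7.0, 13.0, 2.0])
        rows = [x, 3 * x + 2.0, x + 100.0, np.arange(6) * 5.0 + 1, x[::-1], x ** 1.3]
        rho = sparcc(np.vstack(rows), pseudocount=1.0)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_small_m_falls_back_to_clr(self, caplog):
        counts = np.abs(np.random.default_rng(0).normal(10, 3, size=(3, 30)))
        with caplog.at_level("WARNING"):
            rho = sparcc(counts)
        assert any("CLR-Pearson" in r.message for r in caplog.records)
        expected = clr_pearson(counts)
        np.testing.assert_allclose(rho, expected)

    def test_null_noise_envelope(self):
        # 190 independent correlations at N=200 have sd ~ 0.07; max ~ 0.2
        rng = np.random.default_rng(42)
        rho = sparcc(_null_counts(rng))
        off = np.abs(rho - np.eye(20))
        assert off.max() < 0.30

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(42)
        rho = sparcc(_null_counts(rng, block=5, rho=0.8))
        block = rho[:5, :5][np.triu_indices(5, 1)]
        assert 0.6 <= block.mean() <= 0.95

    def test_dataframe_index_preserved(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(20, size=(5, 30)),
                              index=[f"p{i}" for i in range(5)])
        rho = sparcc(counts)
        assert list(rho.index) == [f"p{i}" for i in range(5)]
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sparcc(np.ones((5, 2)))
        with pytest.raises(ValueError):
            sparcc(np.ones((5, 10)), pseudocount=0.0)


class TestBuildNetwork:
    def _corr(self, value):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = value
        return m

    def test_threshold_boundary(self):
        assert len(build_network(self._corr(0.31)).edges) == 1
        assert len(build_network(self._corr(0.30)).edges) == 1  # "0.3 or higher"
        assert len(build_network(self._corr(0.29)).edges) == 0

    def test_all_zero_matrix_edgeless(self):
        net = build_network(np.eye(4) * 0)
        assert net.edges == []
        assert len(net.nodes) == 4  # isolated nodes retained

    def test_threshold_one(self):
        m = self._corr(0.999)
        assert len(build_network(m, threshold=1.0).edges) == 0
        m[0, 1] = m[1, 0] = 1.0
        assert len(build_network(m, threshold=1.0).edges) == 1

    def test_asymmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError):
            build_network(m)


def _net_from_edges(nodes, edges):
    m = np.eye(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for u, v in edges:
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = 0.5
    return build_network(m, node_names=nodes)


class TestExtractModules:
    def test_triangle(self):
        net = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
        mods = extract_modules(net)
        assert len(mods) == 1
        assert mods[0].members == ("a", "b", "c")

    def test_k4_plus_pendant(self):
        edges = list(combinations("abcd", 2)) + [("a", "e"), ("b", "e")]
        net = _net_from_edges(list("abcde"), edges)
        mods = extract_modules(net)
        assert len(mods) == 1
        assert mods[0].seed_members == ("a", "b", "c", "d")
        assert mods[0].attached_members == ("e",)

    def test_two_disjoint_triangles(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        net = _net_from_edges(list("abcxyz"), edges)
        mods = extract_modules(net)
        assert len(mods) == 2
        members = [set(m.members) for m in mods]
        assert {"a", "b", "c"} in members and {"x", "y", "z"} in members
        assert not set(mods[0].members) & set(mods[1].members)

    def test_unattached_nodes_form_no_module(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")]
        net = _net_from_edges(list("abcxy"), edges)
        mods = extract_modules(net)
        assert len(mods) == 1
        assert set(mods[0].members) == {"a", "b", "c"}

    def _brute_force_max_clique_size(self, graph):
        nodes = list(graph.nodes)
        for size in range(len(nodes), 0, -1):
            for combo in combinations(nodes, size):
                if all(graph.has_edge(u, v) for u, v in combinations(combo, 2)):
                    return size
        return 0

    def test_first_seed_matches_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.2, 0.7))
            graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            m = np.eye(n)
            for u, v in graph.edges:
                m[u, v] = m[v, u] = 0.5
            net = build_network(m, node_names=list(range(n)))
            mods = extract_modules(net, min_clique=2)
            if graph.number_of_edges() == 0:
                assert mods == []
            else:
                assert len(mods[0].seed_members) == self._brute_force_max_clique_size(graph)

    def test_modules_node_disjoint_property(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 15
            graph = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            m = np.eye(n)
            for u, v in graph.edges:
                m[u, v] = m[v, u] = 0.5
            net = build_network(m, node_names=list(range(n)))
            mods = extract_modules(net)
            seen = set()
            for mod in mods:
                assert not seen & set(mod.members)
                seen |= set(mod.members)
            assert seen <= set(net.nodes)

    def test_planted_block_lands_in_one_module(self):
        from protscape.synthetic_data import generate_community, simulate_psms, small_config

        config = small_config(seed=13, n_samples_per_phenotype=25,
                              n_specific_per_phenotype=0, block_sigma=1.5)
        community = generate_community(config)
        simulated = simulate_psms(community)
        block = community.truth.coexpression_blocks[0]
        genome = community.protein_genome[block[0]]
        proteins = sorted(p for p, g in community.protein_genome.items() if g == genome)
        samples = sorted(simulated.manifest.samples)
        counts = pd.DataFrame(
            [[simulated.counts.get(p, {}).get(s, 0) for s in samples] for p in proteins],
            index=proteins, columns=samples, dtype=float)
        counts = counts[counts.sum(axis=1) > 0]
        rho = sparcc(counts)
        net = build_network(rho, threshold=0.3)
        mods = extract_modules(net)
        best = max((sum(1 for p in block if p in mod.members) for mod in mods), default=0)
        assert best >= 0.8 * len(block)


class TestModulePhenotype:
    def _manifest(self):
        return SampleManifest(phenotypes={"a1": "AL", "a2": "AL", "c1": "CD", "u1": "UC"})

    def test_dominant_phenotype_assigned(self):
        counts = pd.DataFrame({"a1": [5.0, 4.0], "a2": [5.0, 4.0], "c1": [1.0, 1.0], "u1": [0.0, 0.0]},
                              index=["p", "q"])
        mods = extract_modules(_net_from_edges(["p", "q", "r"],
                                               [("p", "q"), ("q", "r"), ("p", "r")]))
        phenotype, fractions = assign_module_phenotype(mods[0], counts, self._manifest())
        assert phenotype == "AL"
        assert fractions["AL"] == pytest.approx(18 / 20)

    def test_uniform_gives_none(self):
        counts = pd.DataFrame({"a1": [1.0], "a2": [1.0], "c1": [2.0], "u1": [2.0]}, index=["p"])
        mods = [type("M", (), {"members": ("p",)})()]
        phenotype, _ = assign_module_phenotype(mods[0], counts, self._manifest())
        assert phenotype is None

    def test_single_sample_full_dominance(self):
        counts = pd.DataFrame({"c1": [7.0]}, index=["p"])
        mods = [type("M", (), {"members": ("p",)})()]
        phenotype, fractions = assign_module_phenotype(mods[0], counts, self._manifest())
        assert phenotype == "CD"
        assert fractions == {"CD": 1.0}


class TestSuggestPathways:
    def test_union_of_annotated_neighbors(self):
        net = _net_from_edges(["u", "v", "w"], [("u", "v"), ("u", "w"), ("v", "w")])
        mods = extract_modules(net)
        annotations = {"v": {"Glycolysis"}, "w": {"TCA"}}
        suggestions = suggest_pathways(mods[0], net, annotations)
        assert suggestions == {"u": {"Glycolysis", "TCA"}}

    def test_all_unannotated_gives_none(self):
        net = _net_from_edges(["u", "v", "w"], [("u", "v"), ("u", "w"), ("v", "w")])
        mods = extract_modules(net)
        assert suggest_pathways(mods[0], net, {}) == {}

    def test_no_annotated_neighbor(self):
        # path u - v - w, w annotated: u has no annotated neighbor
        net = _net_from_edges(["u", "v", "w", "x"],
                              [("u", "v"), ("v", "w"), ("u", "x"), ("v", "x"), ("u", "w")])
        mods = extract_modules(net)
        annotations = {"x": {"P1"}}
        suggestions = suggest_pathways(mods[0], net, annotations)
        assert "w" not in suggestions  # w-x not an edge
        assert suggestions["u"] == {"P1"} and suggestions["v"] == {"P1"}


def test_modules_table_shape():
    net = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
    table = modules_to_table(extract_modules(net))
    assert list(table.columns) == ["module_id", "protein_id", "role", "phenotype"]
    assert set(table["role"]) == {"seed"}
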