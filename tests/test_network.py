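"""Spearman matrices, exact small-n null, Holm gate, k-core clusters, exports."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemomix import (
    ValidationError,
    build_network,
    extract_clusters,
    export_graph,
    holm_adjust,
    significance_gated_network,
    spearman_matrix,
)
from chemomix.network import (
    CorrelationEdge,
    CorrelationNetwork,
    exact_spearman_p,
    holm_adjust_matrix,
)

from conftest import make_samples, make_table


def _df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"a{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestSpearmanMatrix:
    def test_perfectly_monotone_pairs(self):
        X = _df([[1, 2, 3, 4, 5], [2, 4, 8, 16, 32], [5, 4, 3, 2, 1]])
        rho, p = spearman_matrix(X)
        assert np.isclose(rho.loc["a0", "a1"], 1.0)
        assert np.isclose(rho.loc["a0", "a2"], -1.0)

    def test_ties_equal_rank_then_pearson_oracle(self):
        """With ties, rho equals the Pearson correlation of mid-ranks."""
        rng = np.random.default_rng(27)
        X = rng.integers(0, 4, size=(5, 10)).astype(float)  # many ties
        X += rng.normal(0, 1e-9, X.shape) * 0  # keep exact ties
        rho, _ = spearman_matrix(_df(X))
        for i in range(5):
            for j in range(i + 1, 5):
                ri = stats.rankdata(X[i])
                rj = stats.rankdata(X[j])
                expected = np.corrcoef(ri, rj)[0, 1]
                assert np.isclose(rho.iloc[i, j], expected, atol=1e-12)

    def test_constant_analyte_skipped_with_warning(self):
        X = _df([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7], [5, 3, 4, 1, 2]])
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(X)
        assert list(rho.index) == ["a0", "a2"]

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            spearman_matrix(_df([[1, 2, 3], [3, 2, 1]]))


class TestExactSpearmanNull:
    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_full_enumeration(self, n):
        """Exact p equals the fraction of permutations with |rho| at least
        as large as observed."""
        base = np.arange(n, dtype=float)
        all_rho = [
            np.corrcoef(base, perm)[0, 1]
            for perm in itertools.permutations(range(n))
        ]
        total = math.factorial(n)
        for rho_obs in {round(r, 9) for r in all_rho}:
            brute = sum(1 for r in all_rho if abs(r) >= abs(rho_obs) - 1e-9) / total
            assert np.isclose(exact_spearman_p(rho_obs, n), brute, atol=1e-12)

    def test_more_conservative_than_t_in_far_tail(self):
        from chemomix.network import _t_approx_p

        for rho in (0.9, 0.95, 0.99):
            assert exact_spearman_p(rho, 12) > float(_t_approx_p(np.array(rho), 12))


class TestHolm:
    def test_hand_example(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_single_unchanged(self):
        assert holm_adjust([0.2])[0] == 0.2

    def test_sandwich_and_statsmodels(self):
        """raw <= Holm <= Bonferroni, and equality with statsmodels."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(28)
        for _ in range(500):
            p = rng.uniform(0, 1, rng.integers(1, 11))
            a = holm_adjust(p)
            assert (a >= p - 1e-12).all()
            assert (a <= np.minimum(len(p) * p, 1.0) + 1e-12).all()
            ref = multipletests(p, method="holm")[1]
            assert np.allclose(a, ref, atol=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            holm_adjust([-0.1])


class TestBuildNetwork:
    def _matrices(self, rho_pairs, ids):
        n = len(ids)
        rho = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((n, n)), index=ids, columns=ids)
        for (a, b), (r, q) in rho_pairs.items():
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = q
        return rho, p

    def test_no_significant_pairs_empty(self):
        rho, p = self._matrices({}, ["x", "y", "z"])
        net = build_network(rho, p, 0.05)
        assert net.edges == [] and net.nodes == set()

    def test_complete_graph(self):
        ids = ["a", "b", "c", "d"]
        pairs = {
            (x, y): (0.9, 0.001) for x, y in itertools.combinations(ids, 2)
        }
        rho, p = self._matrices(pairs, ids)
        net = build_network(rho, p, 0.05)
        assert len(net.edges) == 6 and net.nodes == set(ids)

    def test_edge_sign_and_ordering(self):
        rho, p = self._matrices({("y", "x"): (-0.8, 0.01)}, ["x", "y"])
        net = build_network(rho, p, 0.05)
        (e,) = net.edges
        assert (e.analyte_a, e.analyte_b) == ("x", "y")
        assert e.sign == "negative"

    def test_invariant_to_analyte_order(self, default_study):
        from chemomix.normalize import normalise_metabolome

        table = normalise_metabolome(
            default_study.metabolites, default_study.metabolite_is
        )
        sub = table.subset_analytes(table.analyte_ids[:20])
        rho, p = spearman_matrix(sub)
        ph = holm_adjust_matrix(p)
        net1 = build_network(rho, ph, 0.5)
        order = list(reversed(rho.index))
        net2 = build_network(rho.loc[order, order], ph.loc[order, order], 0.5)
        key = lambda n: [(e.analyte_a, e.analyte_b) for e in n.edges]
        assert key(net1) == key(net2)


def _brute_k_core(G, k):
    """Oracle: union of all node subsets inducing min-degree >= k."""
    nodes = list(G.nodes)
    best = set()
    for r in range(k + 1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            H = G.subgraph(subset)
            if H.number_of_nodes() and min(dict(H.degree()).values()) >= k:
                best |= set(subset)
    return best


class TestExtractClusters:
    def _net(self, edges):
        return CorrelationNetwork(
            edges=[
                CorrelationEdge(*sorted(e), rho=0.9, p=0.001, p_holm=0.01)
                for e in edges
            ],
            nodes={n for e in edges for n in e},
        )

    def test_k4_complete(self):
        net = self._net(list(itertools.combinations("abcd", 2)))
        clusters = extract_clusters(net, k=3)
        assert clusters.components == [set("abcd")]
        assert clusters.core_nodes == set("abcd")

    def test_path_of_five_has_empty_3core(self):
        net = self._net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        clusters = extract_clusters(net, k=3)
        assert clusters.components == [set("abcde")]
        assert clusters.core_nodes == set()
        assert clusters.degree["c"] == 2

    def test_matches_brute_force_on_random_graphs(self):
        """k-core equals exhaustive search over <= 10-node random graphs."""
        rng = np.random.default_rng(29)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            G = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            expected = _brute_k_core(G, 3)
            net = self._net([tuple(map(str, e)) for e in G.edges])
            got = extract_clusters(net, k=3).core_nodes
            assert got == {str(v) for v in expected}

    def test_order_independence(self):
        rng = np.random.default_rng(30)
        G = nx.gnp_random_graph(12, 0.3, seed=5)
        edges = [tuple(map(str, e)) for e in G.edges]
        c1 = extract_clusters(self._net(edges), k=3)
        rng.shuffle(edges)
        c2 = extract_clusters(self._net(edges), k=3)
        assert c1.core_nodes == c2.core_nodes
        assert c1.components == c2.components


class TestExportAndGate:
    def test_sif_lines(self, tmp_path):
        net = CorrelationNetwork(
            edges=[CorrelationEdge("a", "b", rho=0.9, p=1e-4, p_holm=0.01)],
            nodes={"a", "b"},
        )
        clusters = extract_clusters(net, k=3)
        path = export_graph(net, clusters, "SIF", tmp_path / "n.sif")
        assert path.read_text() == "a\tpos\tb\n"
        empty = CorrelationNetwork(edges=[], nodes=set())
        path = export_graph(empty, extract_clusters(empty), "SIF",
                            tmp_path / "e.sif")
        assert path.read_text() == ""

    def test_graphml_round_trip(self, tmp_path):
        net = CorrelationNetwork(
            edges=[
                CorrelationEdge("a", "b", rho=0.9, p=1e-4, p_holm=0.01),
                CorrelationEdge("b", "c", rho=-0.8, p=1e-3, p_holm=0.04),
            ],
            nodes={"a", "b", "c"},
        )
        clusters = extract_clusters(net, k=1)
        path = export_graph(net, clusters, "GraphML", tmp_path / "n.graphml")
        G = nx.read_graphml(path)
        assert {frozenset(e) for e in G.edges} == {
            frozenset(("a", "b")), frozenset(("b", "c"))
        }
        assert G.edges["a", "b"]["sign"] == "positive"

    def test_unknown_format(self, tmp_path):
        net = CorrelationNetwork(edges=[], nodes=set())
        with pytest.raises(ValidationError):
            export_graph(net, extract_clusters(net), "DOT", tmp_path / "x")

    def test_gate_conservation(self, default_study):
        """Network nodes are a subset of the significant analytes."""
        from chemomix.integrate import integrate_layers
        from chemomix.normalize import (
            log_transform,
            mean_centre,
            normalise_elementome,
            normalise_metabolome,
        )
        from chemomix.univariate import run_univariate, significant_ids

        el = normalise_elementome(default_study.elements)
        met = normalise_metabolome(
            default_study.metabolites, default_study.metabolite_is
        )
        combined = mean_centre(log_transform(integrate_layers([el, met])))
        sig = significant_ids(run_univariate(combined, test="wilcoxon"))
        net, clusters, _, _ = significance_gated_network(combined, sig)
        assert net.nodes <= set(sig)
        assert clusters.core_nodes <= net.nodes
        for comp in clusters.components:
            assert len(comp) >= 2
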