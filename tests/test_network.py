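"""Distance correlation, permutation inference, tripartite graph, Leiden."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopk.network import (
    build_tripartite_graph,
    detect_communities,
    distance_correlation,
    network_summary,
    permutation_pvalue,
    signed_association_table,
)
from conftest import brute_force_max_modularity, dcor_bruteforce, modularity_of


class TestDistanceCorrelation:
    def test_identical_vectors(self):
        assert distance_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reflection_has_unit_dcor(self):
        # distance matrices coincide; the direction comes from Pearson
        assert distance_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)
        assert np.corrcoef([1, 2, 3], [3, 2, 1])[0, 1] < 0

    def test_pinned_nonlinear_example(self):
        # value pinned by the double-loop oracle before the build
        d = distance_correlation([0, 1, 2, 3], [0, 1, 4, 9])
        assert d == pytest.approx(0.9684641640120555, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=35)
            y = rng.normal(size=35) + 0.5 * x
            assert abs(distance_correlation(x, y) - dcor_bruteforce(x, y)) <= 1e-10

    def test_constant_vector_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert distance_correlation([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]) == 0.0

    @given(
        a=st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + x
        assert distance_correlation(a * x + b, y) == pytest.approx(
            distance_correlation(x, y), abs=1e-10
        )

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(y, x), abs=1e-12
        )


class TestPermutationP:
    def test_self_dependence_hits_floor(self):
        x = np.arange(35.0)
        assert permutation_pvalue(x, x, n_perm=1000, seed=0) == pytest.approx(1 / 1001)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=35), rng.normal(size=35)
        p1 = permutation_pvalue(x, y, n_perm=500, seed=3)
        p2 = permutation_pvalue(x, y, n_perm=500, seed=3)
        assert p1 == p2

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3, 4], [1, 2, 3, 4], n_perm=10)


def _edges_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["metabolite_id", "target_name", "target_class", "dcor", "sign",
                 "p_perm", "q_bh", "phase", "retained"],
    )


class TestAssociationTable:
    def test_threshold_conjunction(self):
        # strong dependence drives q small; d threshold still decides
        rng = np.random.default_rng(21)
        n = 35
        z = rng.normal(size=n)
        abundance = pd.DataFrame(
            {"m_strong": z + 0.05 * rng.normal(size=n),
             "m_weak": 0.35 * z + rng.normal(size=n)},
            index=pd.Index([f"S{i:02d}" for i in range(n)], name="subject_id"),
        )
        targets = pd.DataFrame({"Cmax": z}, index=abundance.index)
        table = signed_association_table(
            abundance, targets, "post", {"Cmax": "pk_parameter"}, n_perm=499, seed=5
        )
        strong = table[table.metabolite_id == "m_strong"].iloc[0]
        weak = table[table.metabolite_id == "m_weak"].iloc[0]
        assert strong.retained and strong.dcor >= 0.5 and strong.sign == "+"
        # small q alone is not enough below the d threshold
        assert weak.dcor < 0.5 and not weak.retained

    def test_subject_mismatch_raises(self):
        abundance = pd.DataFrame({"m": [1.0, 2, 3, 4]},
                                 index=pd.Index(list("abcd"), name="subject_id"))
        targets = pd.DataFrame({"t": [1.0, 2, 3]},
                               index=pd.Index(list("abc"), name="subject_id"))
        with pytest.raises(ValueError, match="mismatch"):
            signed_association_table(abundance, targets, "pre", n_perm=99)

    def test_phase_validated(self):
        with pytest.raises(ValueError, match="phase"):
            signed_association_table(pd.DataFrame(), pd.DataFrame(), "mid")


class TestTripartiteGraph:
    def test_only_retained_edges_enter(self):
        edges = _edges_frame(
            [
                ["m1", "Cmax", "pk_parameter", 0.8, "+", 0.001, 0.01, "post", True],
                ["m2", "Heart rate", "clinical", 0.7, "-", 0.001, 0.01, "post", True],
                ["m3", "Cmax", "pk_parameter", 0.4, "+", 0.2, 0.6, "post", False],
            ]
        )
        g = build_tripartite_graph(edges)
        assert g.number_of_edges() == 2
        assert g.nodes["Cmax"]["type"] == "pk_parameter"
        assert g.nodes["Heart rate"]["type"] == "characteristic"

    def test_empty_edge_list_gives_empty_graph(self):
        g = build_tripartite_graph(_edges_frame([]))
        assert g.number_of_nodes() == 0
        with pytest.raises(ValueError, match="empty"):
            detect_communities(g)

    def test_edge_type_contract(self):
        edges = _edges_frame(
            [
                ["m1", "Cmax", "pk_parameter", 0.8, "+", 0.001, 0.01, "pre", True],
                ["m1", "AST", "laboratory_serum", 0.6, "-", 0.001, 0.01, "pre", True],
                ["m2", "AST", "laboratory_serum", 0.7, "+", 0.001, 0.01, "pre", True],
            ]
        )
        g = build_tripartite_graph(edges)
        for u, v in g.edges:
            types = {g.nodes[u]["type"], g.nodes[v]["type"]}
            assert "metabolite" in types and len(types) == 2

    def test_unknown_target_class_rejected(self):
        edges = _edges_frame(
            [["m1", "x", "mystery", 0.9, "+", 0.001, 0.01, "pre", True]]
        )
        with pytest.raises(ValueError, match="unknown target class"):
            build_tripartite_graph(edges)


def two_block_graph():
    """5 metabolites on Cmax and 4 on systolic pressure, no cross edges."""
    g = nx.Graph()
    rng = np.random.default_rng(3)
    for i in range(5):
        g.add_node(f"ma{i}", type="metabolite")
        g.add_edge(f"ma{i}", "Cmax", weight=0.6 + 0.05 * i)
    g.nodes["Cmax"]["type"] = "pk_parameter"
    for i in range(4):
        g.add_node(f"mb{i}", type="metabolite")
        g.add_edge(f"mb{i}", "Systolic pressure", weight=0.55 + 0.05 * i)
    g.nodes["Systolic pressure"]["type"] = "characteristic"
    return g


class TestCommunities:
    def test_disconnected_stars_form_two_modules(self):
        g = two_block_graph()
        partition = detect_communities(g, seed=0)
        assert len(partition) == 2
        blocks = [frozenset(m) for m in partition.modules]
        expected = [
            frozenset({"Cmax"} | {f"ma{i}" for i in range(5)}),
            frozenset({"Systolic pressure"} | {f"mb{i}" for i in range(4)}),
        ]
        assert set(blocks) == set(expected)

    def test_leiden_matches_bruteforce_max_modularity(self):
        g = two_block_graph()  # 11 nodes: exhaustive search is feasible
        partition = detect_communities(g, seed=1)
        q_leiden = modularity_of(partition.membership, g)
        q_best, _ = brute_force_max_modularity(g)
        assert q_leiden == pytest.approx(q_best, abs=1e-9)

    def test_seeded_determinism(self):
        g = two_block_graph()
        a = detect_communities(g, seed=5).membership
        b = detect_communities(g, seed=5).membership
        assert a == b

    def test_modularity_not_below_components_partition(self, cohort35):
        g = two_block_graph()
        g.add_edge("ma0", "Systolic pressure", weight=0.5)  # weak bridge
        partition = detect_communities(g, seed=2)
        comp_labels = {}
        for c, comp in enumerate(nx.connected_components(g)):
            for v in comp:
                comp_labels[v] = c
        assert modularity_of(partition.membership, g) >= modularity_of(comp_labels, g) - 1e-12

    def test_summary_counts(self):
        g = two_block_graph()
        partition = detect_communities(g, seed=0)
        s = network_summary(g, partition)
        assert s == {
            "n_metabolites": 9,
            "n_pk_parameters": 1,
            "n_characteristics": 1,
            "n_edges": 9,
            "n_modules": 2,
        }
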