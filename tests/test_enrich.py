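"""Over-representation testing, retention filters, hierarchy, integration."""

from itertools import permutations

import pandas as pd
import pytest

from metabopk.datatypes import PathwayFixture, PathwayRecord
from metabopk.enrich import (
    FALLBACK_LABEL,
    filter_pathways,
    integrate_modules_pathways,
    overrepresentation_test,
    rollup_hierarchy,
)
from metabopk.network import CommunityPartition
from conftest import hypergeom_tail_enumeration


def fixture_of(*member_sets, top_levels=None, subs=None):
    records = []
    for i, members in enumerate(member_sets):
        records.append(
            PathwayRecord(
                pathway_id=f"PW{i}",
                source="Reactome",
                pathway_name=f"set {i}",
                top_level=(top_levels or ["Transport of small molecules"] * len(member_sets))[i],
                sub_pathway=(subs or ["SLC-mediated transmembrane transport"] * len(member_sets))[i],
                members=frozenset(members),
            )
        )
    return PathwayFixture(records)


BG20 = [f"M{i:02d}" for i in range(20)]


class TestHypergeometricTail:
    def test_pinned_worked_example(self):
        # N=20, K=5, n=10, k=4: (5*C(15,6)+C(15,5))/C(20,10)
        fx = fixture_of(BG20[:5])
        res = overrepresentation_test(BG20[:4] + BG20[10:16], fx, BG20)
        assert res.loc[0, "n_hits"] == 4
        assert res.loc[0, "p_hyper"] == pytest.approx(28028 / 184756, abs=1e-12)

    def test_zero_hits_gives_p_one(self):
        fx = fixture_of(BG20[:5])
        res = overrepresentation_test(BG20[10:16], fx, BG20)
        assert res.loc[0, "n_hits"] == 0
        assert res.loc[0, "p_hyper"] == pytest.approx(1.0)

    def test_saturated_draw_gives_p_one(self):
        # background equals the pathway: every draw is all hits
        fx = fixture_of(BG20[:8])
        res = overrepresentation_test(BG20[:5], fx, BG20[:8])
        assert res.loc[0, "p_hyper"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n,k", [(8, 3, 4, 2), (10, 4, 5, 3), (12, 5, 6, 2)])
    def test_matches_exhaustive_enumeration_small_universes(self, N, K, n, k):
        universe = [f"x{i}" for i in range(N)]
        fx = fixture_of(universe[:K], subs=None)
        # craft a selection achieving exactly k hits
        selected = universe[:k] + universe[K : K + (n - k)]
        res = overrepresentation_test(selected, fx, universe, size_range=(1, N))
        exact = hypergeom_tail_enumeration(N, K, n, k)
        assert res.loc[0, "p_hyper"] == pytest.approx(float(exact), abs=1e-12)

    def test_selected_outside_background_rejected(self):
        fx = fixture_of(BG20[:5])
        with pytest.raises(ValueError, match="subset"):
            overrepresentation_test(["nope"], fx, BG20)


class TestRetentionFilters:
    def _results(self):
        return pd.DataFrame(
            {
                "pathway_id": ["a", "b", "c", "d", "e"],
                "n_hits": [1, 3, 4, 2, 6],
                "pathway_size": [10, 4, 151, 20, 30],
                "q_bh": [0.001, 0.001, 0.001, 0.2, 0.01],
                "top_level": ["T"] * 5,
                "sub_pathway": ["s"] * 5,
                "hit_ids": ["m1", "m1;m2;m3", "m1;m2;m3;m4", "m1;m2", "m1;m2;m3;m4;m5;m6"],
            }
        )

    def test_single_hit_excluded(self):
        retained = filter_pathways(self._results())
        assert "a" not in set(retained["pathway_id"])

    def test_size_bounds_exclude_regardless_of_p(self):
        retained = set(filter_pathways(self._results())["pathway_id"])
        assert "b" not in retained and "c" not in retained

    def test_conjunction_keeps_qualifying_pathway_only(self):
        assert set(filter_pathways(self._results())["pathway_id"]) == {"e"}

    def test_all_passing_is_identity(self):
        res = self._results().loc[[4]].reset_index(drop=True)
        pd.testing.assert_frame_equal(filter_pathways(res), res)

    def test_filter_order_independence(self):
        res = self._results()
        masks = {
            "hits": res["n_hits"] >= 2,
            "size": (res["pathway_size"] >= 5) & (res["pathway_size"] <= 150),
            "q": res["q_bh"] <= 0.05,
        }
        expected = set(filter_pathways(res)["pathway_id"])
        for order in permutations(masks):
            step = res
            for key in order:
                step = step[masks[key].loc[step.index]]
            assert set(step["pathway_id"]) == expected


class TestRollup:
    def _retained(self):
        return pd.DataFrame(
            {
                "top_level": ["Transport of small molecules", "Signal transduction",
                              "Transport of small molecules"],
                "sub_pathway": ["SLC-mediated transmembrane transport",
                                "Signaling by GPCR",
                                "ABC-family proteins mediated transport"],
                "hit_ids": [";".join(f"m{i}" for i in range(10)), "m1;m2;m3", "m0;m1"],
            }
        )

    def test_largest_group_ranks_first(self):
        out = rollup_hierarchy(self._retained())
        assert out.loc[0, "top_level"] == "Transport of small molecules"
        assert out.loc[0, "n_distinct_metabolites"] == 10

    def test_single_group(self):
        out = rollup_hierarchy(self._retained().iloc[[1]])
        assert len(out) == 1

    def test_ties_alphabetical(self):
        res = pd.DataFrame(
            {
                "top_level": ["Zeta", "Alpha"],
                "sub_pathway": ["s1", "s2"],
                "hit_ids": ["m1;m2", "m3;m4"],
            }
        )
        out = rollup_hierarchy(res)
        assert list(out["top_level"]) == ["Alpha", "Zeta"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rollup_hierarchy(pd.DataFrame(columns=["top_level", "sub_pathway", "hit_ids"]))


def edges_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["metabolite_id", "target_name", "target_class", "dcor", "sign",
                 "p_perm", "q_bh", "phase", "retained"],
    )


class TestIntegration:
    def _retained(self):
        return pd.DataFrame(
            {
                "top_level": ["Transport of small molecules"],
                "sub_pathway": ["SLC-mediated transmembrane transport"],
                "hit_ids": ["m1;m9"],
            }
        )

    def test_shared_module_gets_pathway_label(self):
        partition = CommunityPartition(membership={"m1": 0, "Cmax": 0})
        edges = edges_frame(
            [["m1", "Cmax", "pk_parameter", 0.8, "+", 0.001, 0.01, "post", True]]
        )
        out = integrate_modules_pathways(partition, edges, self._retained(), phase="post")
        assert len(out) == 1
        assert out.loc[0, "top_level_pathways"] == (
            "Transport of small molecules (SLC-mediated transmembrane transport)"
        )

    def test_unannotated_metabolite_gets_fallback_label(self):
        partition = CommunityPartition(membership={"m2": 0, "Cmax": 0})
        edges = edges_frame(
            [["m2", "Cmax", "pk_parameter", 0.7, "-", 0.001, 0.01, "pre", True]]
        )
        out = integrate_modules_pathways(partition, edges, self._retained(), phase="pre")
        assert out.loc[0, "top_level_pathways"] == FALLBACK_LABEL

    def test_cross_module_pairs_are_dropped(self):
        partition = CommunityPartition(membership={"m1": 0, "Cmax": 1})
        edges = edges_frame(
            [["m1", "Cmax", "pk_parameter", 0.8, "+", 0.001, 0.01, "post", True]]
        )
        assert integrate_modules_pathways(partition, edges, self._retained()).empty

    def test_empty_partition_empty_report(self):
        partition = CommunityPartition(membership={})
        assert integrate_modules_pathways(partition, edges_frame([]), self._retained()).empty

    def test_records_traceable_to_retained_edges_and_modules(self):
        partition = CommunityPartition(
            membership={"m1": 0, "Cmax": 0, "m2": 1, "AST": 1}
        )
        edges = edges_frame(
            [
                ["m1", "Cmax", "pk_parameter", 0.8, "+", 0.001, 0.01, "post", True],
                ["m2", "AST", "laboratory_serum", 0.6, "-", 0.001, 0.02, "post", True],
                ["m1", "AST", "laboratory_serum", 0.55, "+", 0.01, 0.2, "post", False],
            ]
        )
        out = integrate_modules_pathways(partition, edges, self._retained(), phase="post")
        retained_pairs = {
            (r.metabolite_id, r.target_name)
            for r in edges[edges.retained].itertuples()
        }
        for row in out.itertuples():
            pair = (row.metabolite, row.parameter_or_characteristic)
            assert pair in retained_pairs
            assert partition.membership[pair[0]] == partition.membership[pair[1]]
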