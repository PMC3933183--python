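"""Homolog clustering: hit filtering, single linkage, stringency refinement,
split-gene merging, inverted-repeat resolution, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidphylo.clustering import (
    ClusterSet,
    cluster_single_linkage,
    filter_hits,
    merge_split_genes,
    multicopy_taxa,
    occupancy_filter,
    refine_multicopy,
    resolve_ir_duplicates,
    stringency_schedule,
)
from plastidphylo.types import PlastidPhyloError, SimilarityHit


def hit(q, t, ev, qc=0.9, tc=0.9):
    return SimilarityHit(query_id=q, target_id=t, evalue=ev,
                         query_cov=qc, target_cov=tc)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ev,qc,tc,kept",
        [
            (1e-6, 0.5, 0.5, True),    # passes both thresholds
            (1e-4, 0.9, 0.9, False),   # e-value above 1e-5
            (1e-10, 0.39, 0.9, False), # query coverage below 0.40
            (1e-5, 0.4, 0.4, True),    # boundary: <= and >= are inclusive
        ],
    )
    def test_default_thresholds(self, ev, qc, tc, kept):
        edges = filter_hits([hit("a", "b", ev, qc, tc)])
        assert bool(edges) is kept

    def test_self_hits_dropped_and_reciprocal_collapsed(self):
        edges = filter_hits([
            hit("a", "a", 1e-20),
            hit("a", "b", 1e-6),
            hit("b", "a", 1e-9),
        ])
        assert edges == [("a", "b", 1e-9)]


def brute_force_components(nodes, edges):
    """Transitive-closure oracle for connected components."""
    comp = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b, _ in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for n in merged:
                    comp[n] = merged
                changed = True
    return {frozenset(c) for c in comp.values()}


class TestSingleLinkage:
    def test_path_connected_sequences_cluster(self):
        cs = cluster_single_linkage(
            ["A", "B", "C", "D"], [("A", "B", 1e-9), ("B", "C", 1e-9)]
        )
        assert sorted(map(sorted, cs.clusters.values())) == [["A", "B", "C"], ["D"]]

    def test_no_edges_gives_singletons(self):
        cs = cluster_single_linkage(list("ABC"), [])
        assert all(len(m) == 1 for m in cs.clusters.values())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n=st.integers(2, 50),
        edges=st.lists(st.tuples(st.integers(0, 49), st.integers(0, 49)),
                       max_size=80),
        )
    def test_matches_transitive_closure_oracle(self, n, edges):
        nodes = [f"n{i}" for i in range(n)]
        edge_list = [
            (f"n{a % n}", f"n{b % n}", 1e-9) for a, b in edges if a % n != b % n
        ]
        got = cluster_single_linkage(nodes, edge_list)
        expected = brute_force_components(nodes, edge_list)
        assert {frozenset(c) for c in got.clusters.values()} == expected


class TestRefineMulticopy:
    def _hits(self):
        # gene 1 = {x|a, y|a}; gene 2 = {x|b, z|b}; taxon x has a paralog
        # pair joined only by a weak 1e-6 edge
        return [
            hit("x|a", "y|a", 1e-20),
            hit("x|b", "z|b", 1e-20),
            hit("x|a", "x|b", 1e-6),
        ]

    def test_paralogs_split_at_stricter_cutoff(self):
        members = ["x|a", "y|a", "x|b", "z|b"]
        out = refine_multicopy(members, self._hits())
        groups = sorted(sorted(m) for m in out.clusters.values())
        assert groups == [["x|a", "y|a"], ["x|b", "z|b"]]

    def test_cluster_without_multicopy_unchanged(self):
        members = ["x|a", "y|a"]
        out = refine_multicopy(members, [hit("x|a", "y|a", 1e-20)])
        assert list(out.clusters.values()) == [["x|a", "y|a"]]

    def test_connected_at_floor_drops_offending_taxon(self):
        members = ["x|a", "y|a", "x|b", "z|b"]
        hits = [
            hit("x|a", "y|a", 1e-40),
            hit("x|b", "z|b", 1e-40),
            hit("x|a", "x|b", 1e-40),
            hit("y|a", "z|b", 1e-40),
        ]
        # x's copies are inseparably connected at every cutoff, but the
        # link is cross-gene (not an IR-grade within-taxon hit)
        out = refine_multicopy(members, hits, ir_evalue=1e-200)
        all_members = [m for ms in out.clusters.values() for m in ms]
        assert "x|a" not in all_members and "x|b" not in all_members
        assert {"y|a", "z|b"} <= set(all_members)
        assert any(e["action"] == "drop_multicopy_taxa" for e in out.provenance)

    def test_empty_schedule_rejected(self):
        with pytest.raises(PlastidPhyloError, match="schedule"):
            refine_multicopy(["x|a", "x|b"], [], schedule=[])

    def test_refinement_never_increases_multicopy_taxa(self):
        members = ["x|a", "y|a", "x|b", "z|b", "w|a"]
        hits = self._hits() + [hit("w|a", "y|a", 1e-18)]
        before = len(multicopy_taxa(members))
        out = refine_multicopy(members, hits)
        after = max(
            (len(multicopy_taxa(ms)) for ms in out.clusters.values()),
            default=0,
        )
        assert after <= before

    def test_stricter_cutoff_refines_partition(self):
        # clustering at a stricter e-value always yields a partition that
        # refines (is nested within) the looser one
        members = ["a|1", "b|1", "c|1", "d|1"]
        hits = [
            hit("a|1", "b|1", 1e-20), hit("b|1", "c|1", 1e-10),
            hit("c|1", "d|1", 1e-6),
        ]
        loose = cluster_single_linkage(
            members, filter_hits(hits, max_evalue=1e-5))
        strict = cluster_single_linkage(
            members, filter_hits(hits, max_evalue=1e-15))
        for sm in strict.clusters.values():
            assert any(set(sm) <= set(lm) for lm in loose.clusters.values())


class TestMergeSplitGenes:
    def _clusters(self):
        return ClusterSet(clusters={
            "c1": ["t1|x", "t2|x"],
            "c2": ["t3|y", "t4|y"],
        })

    def test_same_label_disjoint_taxa_merged(self):
        ann = {"t1|x": "rbcL", "t2|x": "rbcL", "t3|y": "rbcL", "t4|y": "rbcL"}
        out = merge_split_genes(self._clusters(), ann)
        assert len(out.clusters) == 1
        assert sorted(out.clusters["c1"]) == ["t1|x", "t2|x", "t3|y", "t4|y"]

    def test_overlapping_taxa_flagged_not_merged(self):
        cs = ClusterSet(clusters={
            "c1": ["t1|x", "t2|x"],
            "c2": ["t2|y", "t3|y"],
        })
        ann = {s: "rbcL" for c in cs.clusters.values() for s in c}
        out = merge_split_genes(cs, ann)
        assert len(out.clusters) == 2
        assert any(e["action"] == "merge_candidate_overlap"
                   for e in out.provenance)

    def test_no_annotations_is_identity(self):
        cs = self._clusters()
        assert merge_split_genes(cs, None).clusters == cs.clusters


class TestResolveIrDuplicates:
    def test_identical_pair_keeps_one(self):
        seqs = {"t1|g": "MKV", "t1|g_ir": "MKV", "t2|g": "MKL"}
        kept = resolve_ir_duplicates(list(seqs), seqs)
        assert kept == ["t1|g", "t2|g"]

    def test_divergent_pair_drops_both(self):
        seqs = {"t1|g": "MKV", "t1|g_ir": "MRV", "t2|g": "MKL"}
        kept = resolve_ir_duplicates(list(seqs), seqs)
        assert kept == ["t2|g"]

    def test_three_copies_any_difference_drops_all(self):
        seqs = {"t1|a": "MKV", "t1|b": "MKV", "t1|c": "MRV"}
        assert resolve_ir_duplicates(list(seqs), seqs) == []

    def test_single_copy_untouched(self):
        seqs = {"t1|g": "MKV"}
        assert resolve_ir_duplicates(["t1|g"], seqs) == ["t1|g"]


class TestOccupancyFilter:
    def _cluster_with(self, n_taxa_present):
        return ClusterSet(clusters={
            "c1": [f"t{i}|g" for i in range(n_taxa_present)]
        })

    def test_exactly_half_retained(self):
        out = occupancy_filter(self._cluster_with(180), 360)
        assert "c1" in out.clusters

    def test_one_below_half_dropped(self):
        out = occupancy_filter(self._cluster_with(179), 360)
        assert out.clusters == {}

    def test_zero_threshold_keeps_everything(self):
        out = occupancy_filter(self._cluster_with(1), 360, min_frac=0.0)
        assert "c1" in out.clusters

    def test_invalid_taxon_count_rejected(self):
        with pytest.raises(PlastidPhyloError):
            occupancy_filter(self._cluster_with(1), 0)


def test_stringency_schedule_divides_by_ten_to_floor():
    s = stringency_schedule(1e-5, 10.0, 1e-30)
    assert s[0] == pytest.approx(1e-6)
    assert s[-1] == pytest.approx(1e-30)
    assert len(s) == 25
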