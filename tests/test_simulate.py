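"""Synthetic-data generator: determinism, tree sampling, GC structure,
missingness calibration, duplicates/paralogs, hit-table construction."""

import dataclasses
import math

import numpy as np
import pytest

from plastidphylo.build import translate_cds
from plastidphylo.clustering import cluster_pipeline, filter_hits
from plastidphylo.composition import composition_table
from plastidphylo.io import write_newick
from plastidphylo.simulate import (
    GcShift,
    SimConfig,
    apply_missingness,
    inject_duplicates_and_paralogs,
    make_hit_table,
    sample_tree,
    simulate_dataset,
    simulate_gene,
)
from plastidphylo.types import Alignment, PlastidPhyloError


class TestSampleTree:
    def test_leaf_and_edge_counts(self):
        t = sample_tree(5, seed=1)
        assert len(t.leaf_nodes()) == 5
        # 2n-3 edges in the unrooted sense: count via bipartition structure
        edges = [
            e for e in t.preorder_edge_iter()
            if e.tail_node is not None and e.length is not None
        ]
        assert len(edges) in (2 * 5 - 3, 2 * 5 - 2)  # rooted rep has 1 extra

    def test_same_seed_identical_newick(self):
        a = write_newick(sample_tree(8, seed=3))
        b = write_newick(sample_tree(8, seed=3))
        assert a == b
        c = write_newick(sample_tree(8, seed=4))
        assert a != c

    def test_mean_branch_length_calibrated(self):
        target = 0.12
        means = []
        for seed in range(40):
            t = sample_tree(6, seed=seed, mean_branch_length=target)
            ls = [e.length for e in t.preorder_edge_iter() if e.length]
            means.append(np.mean(ls))
        # rescaling is exact per tree, so every mean equals the target
        assert np.allclose(means, target)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PlastidPhyloError):
            sample_tree(2, seed=0)


class TestSimulateGene:
    def _tree(self, n=16, seed=2):
        return sample_tree(n, seed=seed, mean_branch_length=0.08)

    def test_output_is_aligned_stop_free_cds(self):
        tree = self._tree()
        genes = simulate_gene(tree, 100, SimConfig(), seed=5)
        lengths = {len(s) for s in genes.values()}
        assert lengths == {300}
        for s in genes.values():
            translate_cds(s)  # raises on any internal stop

    def test_stationary_gc_near_base_composition(self):
        cfg = SimConfig(site_rate_alpha=5.0)
        tree = self._tree()
        genes = simulate_gene(tree, 2000, cfg, seed=6)
        taxa = sorted(genes)
        aln = Alignment(taxa, [genes[t] for t in taxa], "nt")
        gc = composition_table(aln).gc
        base_gc = cfg.base_freqs[1] + cfg.base_freqs[2]
        # binomial-ish scatter around the stationary value
        assert abs(gc.mean() - base_gc) < 0.03

    def test_shifted_clade_hits_gc3_target(self):
        tree = self._tree()
        clade = None
        for nd in tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
            if 4 <= len(leaves) <= 8:
                clade = leaves
                break
        shift = GcShift(clade=clade, targets={3: 0.8})
        cfg = SimConfig()
        genes = simulate_gene(tree, 2000, cfg, shifts=[shift], seed=7)
        taxa = sorted(genes)
        aln = Alignment(
            taxa, [genes[t] for t in taxa], "nt",
            codon_phase=np.tile([1, 2, 3], 2000),
        )
        gc3 = composition_table(aln, "pos3").gc
        shifted = gc3.loc[sorted(clade)].mean()
        assert abs(shifted - 0.8) < 0.05
        others = gc3.drop(index=sorted(clade)).mean()
        assert others < 0.55

    def test_full_determinism(self):
        cfg = SimConfig(seed=9, n_taxa=10, n_genes=3, codon_mean=80)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.genes == b.genes
        assert a.hits == b.hits
        assert a.coverage.present.tolist() == b.coverage.present.tolist()
        assert write_newick(a.tree) == write_newick(b.tree)


class TestApplyMissingness:
    def _genes(self, n_taxa=20, n_genes=6, L=30):
        taxa = [f"t{i:02d}" for i in range(n_taxa)]
        return {
            f"g{j}": {t: "ATG" * L for t in taxa} for j in range(n_genes)
        }

    def test_full_occupancy_removes_nothing(self):
        cfg = SimConfig(min_occupancy=1.0)
        out, cov = apply_missingness(self._genes(), cfg, seed=0)
        assert cov.present.all()
        assert all(len(v) == 20 for v in out.values())

    def test_coverage_matrix_matches_deletions(self):
        cfg = SimConfig()
        out, cov = apply_missingness(self._genes(), cfg, seed=1)
        for gi, gene in enumerate(cov.genes):
            present = {cov.taxa[j] for j in np.flatnonzero(cov.present[gi])}
            assert present == set(out[gene])

    def test_occupancy_floor_respected(self):
        cfg = SimConfig()
        out, cov = apply_missingness(self._genes(), cfg, seed=2)
        for gi in range(cov.n_genes):
            assert cov.present[gi].sum() >= math.ceil(0.5 * cov.n_taxa)

    def test_global_missingness_near_target(self):
        """Averaged over replicates, realized missingness lands near the
        15.6% the occupancy distribution was calibrated to."""
        fractions = []
        for seed in range(5):
            ds = simulate_dataset(SimConfig(seed=seed))
            fractions.append(ds.aligned_matrix().missing_fraction())
        assert abs(np.mean(fractions) - 0.156) < 0.02


class TestDuplicatesAndParalogs:
    def _pruned(self, n_taxa=10):
        taxa = [f"t{i:02d}" for i in range(n_taxa)]
        rng = np.random.default_rng(0)
        genes = {}
        for j in range(3):
            genes[f"g{j}"] = {
                t: "".join(
                    np.random.default_rng(j * 100 + i).choice(
                        ["ATG", "AAA", "GTT", "CTT", "CGT", "GGT"], size=40
                    )
                )
                for i, t in enumerate(taxa)
            }
        return genes

    def test_every_taxon_duplicated_and_resolved(self):
        cfg = SimConfig(ir_dup_rate=1.0, ir_divergence_rate=0.0,
                        paralog_rate=0.0)
        out, truth = inject_duplicates_and_paralogs(self._pruned(), cfg, seed=1)
        for gene, members in out.items():
            taxa = {s.split("|")[0] for s in members}
            assert len(members) == 2 * len(taxa)
        # downstream IR rule keeps exactly one copy per taxon
        from plastidphylo.clustering import resolve_ir_duplicates

        for gene, members in out.items():
            kept = resolve_ir_duplicates(sorted(members), members)
            assert len(kept) == len({s.split("|")[0] for s in members})

    def test_divergent_copy_dropped_with_taxon(self):
        cfg = SimConfig(ir_dup_rate=1.0, ir_divergence_rate=1.0,
                        paralog_rate=0.0)
        out, truth = inject_duplicates_and_paralogs(self._pruned(), cfg, seed=2)
        from plastidphylo.clustering import resolve_ir_duplicates

        for gene, members in out.items():
            assert resolve_ir_duplicates(sorted(members), members) == []
        assert truth.divergent_ir  # actions recorded

    def test_paralog_truth_labels_partition_into_two_genes(self):
        cfg = SimConfig(ir_dup_rate=0.0, paralog_rate=1.0)
        out, truth = inject_duplicates_and_paralogs(self._pruned(), cfg, seed=3)
        labels = set(truth.gene_of.values())
        assert {"g0", "g0p"} <= labels
        assert frozenset({"g0", "g0p"}) in truth.paralog_pairs


class TestMakeHitTable:
    def _truth(self):
        cfg = SimConfig(ir_dup_rate=0.0, paralog_rate=0.0)
        genes, truth = inject_duplicates_and_paralogs(
            {
                "g0": {f"t{i}": "ATGAAA" for i in range(4)},
                "g1": {f"t{i}": "ATGGGT" for i in range(4)},
            },
            cfg, seed=0,
        )
        lengths = {sid: 2 for g in genes.values() for sid in g}
        return truth, lengths

    def test_false_positives_fail_default_filter(self):
        truth, lengths = self._truth()
        hits = make_hit_table(lengths, truth, fp_rate=0.9, fn_rate=0.0, seed=1)
        fp = [h for h in hits
              if truth.gene_of[h.query_id] != truth.gene_of[h.target_id]]
        assert fp  # spurious hits were generated ...
        assert all(h.evalue > 1e-5 for h in fp)  # ... above the cutoff
        edges = filter_hits(hits)
        for a, b, _ in edges:
            assert truth.gene_of[a] == truth.gene_of[b]

    def test_total_false_negatives_leave_singletons(self):
        truth, lengths = self._truth()
        hits = make_hit_table(lengths, truth, fn_rate=1.0, seed=2)
        edges = filter_hits(hits)
        assert edges == []

    def test_clean_table_recovers_truth_exactly(self):
        cfg = SimConfig(seed=4, n_taxa=12, n_genes=4, codon_mean=80,
                        fp_rate=0.0, fn_rate=0.0, ir_dup_rate=0.0,
                        paralog_rate=0.0)
        ds = simulate_dataset(cfg)
        aa = {r.seq_id: r.seq for r in ds.aa_records}
        clus = cluster_pipeline(ds.hits, sorted(aa), sequences=aa,
                                n_taxa=cfg.n_taxa)
        got = {frozenset(m) for m in clus.clusters.values()}
        want = {
            frozenset(sid for sid, g in ds.truth.gene_of.items() if g == gene)
            for gene in set(ds.truth.gene_of.values())
        }
        assert got == want

    def test_invalid_rates_rejected(self):
        truth, lengths = self._truth()
        with pytest.raises(PlastidPhyloError):
            make_hit_table(lengths, truth, fp_rate=1.0)
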