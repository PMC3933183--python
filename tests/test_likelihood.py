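"""Partitioned likelihood engine: pruning against closed forms and an
enumeration oracle, parameter counting, AICc, scheme comparison,
nuisance-parameter fitting."""

import math
from itertools import product

import numpy as np
import pytest

from plastidphylo.coding import single_partition_scheme
from plastidphylo.io import parse_newick
from plastidphylo.likelihood import (
    aicc,
    compare_schemes,
    count_parameters,
    evaluate_scheme,
    log_likelihood,
    optimize_nuisance,
)
from plastidphylo.simulate import sample_tree, simulate_gtr_alignment
from plastidphylo.substmodels import (
    discrete_gamma,
    gtr_model,
    transition_matrix,
)
from plastidphylo.types import (
    Alignment,
    GTR_G,
    LikelihoodResult,
    Partition,
    PartitionScheme,
    PlastidPhyloError,
)

JC = gtr_model(alpha=1e6, ncat=1)


class TestClosedForms:
    def test_identical_single_site_zero_branches(self):
        tree = parse_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], ["A", "A"], "nt")
        lnl = log_likelihood(tree, aln, single_partition_scheme(1),
                             {"all": JC})
        assert lnl == pytest.approx(math.log(0.25))

    @pytest.mark.parametrize("t", [0.05, 0.37, 1.4])
    def test_two_taxon_jc_mismatch_site(self, t):
        # site (A, C) under Jukes-Cantor: L = (1/16)(1 - exp(-4t/3))
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = Alignment(["A", "B"], ["A", "C"], "nt")
        lnl = log_likelihood(tree, aln, single_partition_scheme(1),
                             {"all": JC})
        assert lnl == pytest.approx(
            math.log((1 / 16) * (1 - math.exp(-4 * t / 3))), abs=1e-10
        )

    def test_gap_site_contributes_stationary_probability(self):
        tree = parse_newick("(A:0.2,B:0.2);")
        aln = Alignment(["A", "B"], ["A", "-"], "nt")
        lnl = log_likelihood(tree, aln, single_partition_scheme(1),
                             {"all": JC})
        assert lnl == pytest.approx(math.log(0.25))


def enumeration_lnl(tree_newick, aln, model):
    """Brute-force likelihood: sum over all internal-state assignments.

    Independent of the pruning implementation: walks the dendropy tree,
    enumerates every combination of internal node states per site and per
    gamma category.
    """
    tree = parse_newick(tree_newick)
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = {nd: aln.row(nd.taxon.label) for nd in nodes if nd.is_leaf()}
    rates, probs = discrete_gamma(model.alpha, model.ncat)
    n_states = model.n_states
    idx = {c: i for i, c in enumerate("ACGT")}
    total = 0.0
    for site in range(aln.n_columns):
        site_l = 0.0
        for rate, prob in zip(rates, probs):
            pmat = {
                id(nd): transition_matrix(model, (nd.edge.length or 0) * rate)
                for nd in nodes if nd.parent_node is not None
            }
            acc = 0.0
            for assign in product(range(n_states), repeat=len(internal)):
                state = {id(nd): s for nd, s in zip(internal, assign)}
                for nd, row in leaves.items():
                    state[id(nd)] = idx[row[site]]
                term = model.freqs[state[id(tree.seed_node)]]
                for nd in nodes:
                    if nd.parent_node is not None:
                        term *= pmat[id(nd)][
                            state[id(nd.parent_node)], state[id(nd)]
                        ]
                acc += term
            site_l += prob * acc
        total += math.log(site_l)
    return total


class TestEnumerationOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 6))
        tree = sample_tree(n_taxa, seed=seed, mean_branch_length=0.3)
        newick = tree.as_string(schema="newick").strip()
        model = gtr_model(rng.uniform(0.2, 3.0, 6), rng.dirichlet(np.ones(4)),
                          alpha=float(rng.uniform(0.3, 2.0)))
        aln = simulate_gtr_alignment(tree, model, 15, seed=seed + 100)
        got = log_likelihood(tree, aln,
                             single_partition_scheme(aln.n_columns),
                             {"all": model})
        expected = enumeration_lnl(newick, aln, model)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_rerooting(self):
        tree = sample_tree(6, seed=3, mean_branch_length=0.2)
        model = gtr_model(np.array([1.5, 3.0, 0.7, 1.2, 4.1, 1.0]),
                          np.array([0.3, 0.2, 0.2, 0.3]), alpha=0.8)
        aln = simulate_gtr_alignment(tree, model, 200, seed=11)
        sch = single_partition_scheme(200)
        base = log_likelihood(tree, aln, sch, {"all": model})
        tree2 = tree.clone(depth=1)
        leaf = next(tree2.leaf_node_iter())
        half = leaf.edge.length / 2
        tree2.reroot_at_edge(leaf.edge, length1=half, length2=half,
                             update_bipartitions=False)
        again = log_likelihood(tree2, aln, sch, {"all": model})
        assert again == pytest.approx(base, abs=1e-6)

    def test_partition_sum_equals_whole(self):
        tree = sample_tree(5, seed=4)
        model = gtr_model(alpha=0.9)
        aln = simulate_gtr_alignment(tree, model, 120, seed=12)
        whole = log_likelihood(tree, aln, single_partition_scheme(120),
                               {"all": model})
        split = PartitionScheme("halves", [
            Partition("h1", np.arange(60), GTR_G),
            Partition("h2", np.arange(60, 120), GTR_G),
        ])
        parts = log_likelihood(tree, aln, split, {"h1": model, "h2": model})
        assert parts == pytest.approx(whole, abs=1e-8)


class TestParameterCounting:
    def _scheme(self, n_parts, family=GTR_G, cols_per=10):
        return PartitionScheme("s", [
            Partition(f"p{i}", np.arange(i * cols_per, (i + 1) * cols_per),
                      family)
            for i in range(n_parts)
        ])

    def test_single_gtr_partition_360_taxa(self):
        assert count_parameters(self._scheme(1), 360) == 717 + 9

    def test_codon_gene_partitions_360_taxa(self):
        assert count_parameters(self._scheme(234), 360) == 717 + 234 * 9

    def test_binary_partition_four_taxa(self):
        from plastidphylo.types import BIN_G

        assert count_parameters(self._scheme(1, BIN_G), 4) == 5 + 2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PlastidPhyloError):
            count_parameters(self._scheme(1), 2)


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-100.0, 5, 100) == pytest.approx(210 + 60 / 94)

    def test_zero_parameters(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_large_n_approaches_aic(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(PlastidPhyloError):
            aicc(-100.0, 99, 100)


class TestCompareSchemes:
    @staticmethod
    def _result(name, lnl, k, n):
        return LikelihoodResult(scheme_name=name, n_partitions=1, lnL=lnl,
                                k=k, n=n, AICc=aicc(lnl, k, n))

    def test_single_result_delta_zero(self):
        df = compare_schemes([self._result("only", -10, 2, 100)])
        assert df["dAICc"].tolist() == [0.0]

    def test_argmin_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        results = [
            self._result(f"s{i}", float(-rng.uniform(50, 500)),
                         int(rng.integers(1, 20)), 1000)
            for i in range(12)
        ]
        df = compare_schemes(results)
        best_by_scan = min(results, key=lambda r: (r.AICc, r.k))
        assert df.iloc[0]["scheme"] == best_by_scan.scheme_name

    def test_mixed_n_rejected(self):
        with pytest.raises(PlastidPhyloError, match="different n"):
            compare_schemes([
                self._result("a", -10, 2, 100),
                self._result("b", -10, 2, 200),
            ])


class TestOptimizeNuisance:
    def test_gamma_shape_recovered_within_20_percent(self):
        """Six taxa, 2000 codons simulated at alpha = 0.5: the fitted shape
        lands within +-20%."""
        tree = sample_tree(6, seed=5, mean_branch_length=0.15)
        true = gtr_model(np.array([1.2, 3.0, 0.8, 1.1, 4.0, 1.0]),
                         np.array([0.31, 0.18, 0.21, 0.30]), alpha=0.5)
        aln = simulate_gtr_alignment(tree, true, 6000, seed=9)
        fit = optimize_nuisance(tree, aln, single_partition_scheme(6000),
                                max_rounds=4)
        assert 0.4 <= fit.models["all"].alpha <= 0.6

    def test_trajectory_monotone_nondecreasing(self):
        tree = sample_tree(5, seed=6)
        aln = simulate_gtr_alignment(tree, gtr_model(alpha=0.7), 400, seed=10)
        fit = optimize_nuisance(tree, aln, single_partition_scheme(400),
                                max_rounds=4)
        assert all(b >= a - 1e-9
                   for a, b in zip(fit.trajectory, fit.trajectory[1:]))

    def test_refitting_from_optimum_barely_moves(self):
        tree = sample_tree(5, seed=7)
        aln = simulate_gtr_alignment(tree, gtr_model(alpha=0.7), 400, seed=13)
        sch = single_partition_scheme(400)
        first = optimize_nuisance(tree, aln, sch, max_rounds=8)
        again = optimize_nuisance(tree, aln, sch, models=first.models,
                                  max_rounds=2)
        assert again.lnL - first.lnL < 1e-2

    def test_evaluate_scheme_produces_consistent_record(self):
        tree = sample_tree(5, seed=8)
        aln = simulate_gtr_alignment(tree, gtr_model(alpha=0.7), 300, seed=14)
        res = evaluate_scheme(tree, aln, single_partition_scheme(300),
                              max_rounds=2)
        assert res.n == 300
        assert res.k == count_parameters(single_partition_scheme(300), 5)
        assert res.AICc == pytest.approx(aicc(res.lnL, res.k, res.n))
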