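"""Bipartition bookkeeping and majority-rule consensus summaries.

A fully resolved unrooted binary tree on T taxa has T-3 internal
bipartitions (splits); bootstrap support for a split is the fraction of a
tree set containing it.  The majority-rule consensus keeps splits whose
frequency strictly exceeds the cutoff (>0.5 guarantees pairwise
compatibility), labelled with their percentage support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy

from .decisiveness import _adjacency_from_tree, _subtree_leaves
from .types import PlastidPhyloError


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical splits of a tree, one per internal edge.

    Each split is represented by the side *not* containing the reference
    taxon (the lexicographically first leaf label), so the same split from
    different trees compares equal.  Trees with < 4 leaves have none.
    """
    adj, leaf_name = _adjacency_from_tree(tree)
    labels = sorted(leaf_name.values())
    if len(labels) < 4:
        return set()
    ref = labels[0]
    out = set()
    for u in adj:
        for v in adj[u]:
            if u >= v or u in leaf_name or v in leaf_name:
                continue
            side = _subtree_leaves(adj, leaf_name, v, u)
            if ref in side:
                side = set(labels) - side
            if 1 < len(side) < len(labels) - 1:
                out.add(frozenset(side))
    return out


@dataclass
class BipartitionTable:
    """Split counts over a tree set."""

    counts: dict[frozenset, int]
    n_trees: int
    taxa: list[str]

    def frequency(self, split: frozenset) -> float:
        return self.counts.get(split, 0) / self.n_trees


def count_bipartitions(trees: Sequence[dendropy.Tree]) -> BipartitionTable:
    if not trees:
        raise PlastidPhyloError("empty tree set")
    taxon_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter())
                  for t in trees]
    if len(set(taxon_sets)) != 1:
        raise PlastidPhyloError("trees are on different taxon sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    return BipartitionTable(counts=counts, n_trees=len(trees),
                            taxa=sorted(taxon_sets[0]))


def _build_consensus(taxa: Sequence[str], clusters: dict[frozenset, float]) -> dendropy.Tree:
    """Assemble a tree from compatible clusters (splits away from the
    reference taxon), annotating support percentages."""
    ns = dendropy.TaxonNamespace(list(taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    node_of = {}
    # larger clusters first so parents exist before children
    for cl in sorted(clusters, key=len, reverse=True):
        node = dendropy.Node()
        node.label = f"{round(clusters[cl] * 100)}"
        node_of[cl] = node
        parent = root
        best = None
        for other, nd in node_of.items():
            if other != cl and cl < other and (best is None or len(other) < len(best)):
                best, parent = other, nd
        parent.add_child(node)
    for label in taxa:
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        parent = root
        best = None
        for cl, nd in node_of.items():
            if label in cl and (best is None or len(cl) < len(best)):
                best, parent = cl, nd
        parent.add_child(leaf)
    tree.is_rooted = False
    return tree


def majority_rule_consensus(
    trees: Sequence[dendropy.Tree], cutoff: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus: splits with frequency strictly > cutoff.

    ``cutoff`` must be in [0.5, 1]; at >0.5 retained splits are pairwise
    compatible by the pigeonhole argument.  Internal node labels carry the
    rounded percentage support.
    """
    if not (0.5 <= cutoff <= 1.0):
        raise PlastidPhyloError("cutoff must be in [0.5, 1]")
    table = count_bipartitions(trees)
    kept = {
        split: table.frequency(split)
        for split in table.counts
        if table.frequency(split) > cutoff
    }
    splits = list(kept)
    for i in range(len(splits)):           # sanity: pairwise compatibility
        for j in range(i + 1, len(splits)):
            a, b = splits[i], splits[j]
            if a & b and not (a <= b or b <= a):
                raise PlastidPhyloError(
                    "incompatible splits retained (cutoff <= 0.5?)"
                )
    return _build_consensus(table.taxa, kept)


def consensus_support_values(tree: dendropy.Tree) -> list[float]:
    """Support percentages parsed from internal-node labels."""
    out = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label is None:
            continue
        try:
            out.append(float(nd.label))
        except ValueError:
            continue
    return out


@dataclass(frozen=True)
class SupportSummary:
    n_resolved: int
    n_possible: int
    mean_support: float
    threshold: float

    @property
    def fraction_resolved(self) -> float:
        return self.n_resolved / self.n_possible


def support_summary(
    supports: Sequence[float],
    n_taxa: int,
    threshold: float = 70.0,
) -> SupportSummary:
    """Count splits supported at >= threshold percent out of the T-3
    possible on a fully resolved unrooted tree."""
    if n_taxa < 4:
        raise PlastidPhyloError("support summary needs >= 4 taxa")
    n_possible = n_taxa - 3
    n_resolved = sum(1 for s in supports if s >= threshold)
    mean = sum(supports) / len(supports) if supports else 0.0
    return SupportSummary(
        n_resolved=n_resolved, n_possible=n_possible,
        mean_support=mean, threshold=threshold,
    )


def root_at_split(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root the tree on the edge separating ``outgroup`` from the rest.

    The outgroup must form one side of an existing bipartition (i.e. be
    monophyletic in the unrooted tree); otherwise an error is raised.
    """
    out = set(outgroup)
    tree = tree.clone(depth=1)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if not out <= leaves:
        raise PlastidPhyloError(f"unknown outgroup taxa: {sorted(out - leaves)}")
    if out == leaves:
        raise PlastidPhyloError("outgroup cannot be the whole taxon set")
    if len(out) == 1:
        label = next(iter(out))
        leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        edge = leaf.edge
    else:
        edge = None
        for e in tree.preorder_edge_iter():
            if e.tail_node is None:
                continue
            side = {l.taxon.label for l in e.head_node.leaf_iter()}
            if side == out or side == leaves - out:
                edge = e
                break
        if edge is None:
            raise PlastidPhyloError(
                "outgroup is not monophyletic: no matching bipartition"
            )
    length = edge.length if edge.length is not None else None
    tree.reroot_at_edge(
        edge,
        length1=None if length is None else length / 2,
        length2=None if length is None else length / 2,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree
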