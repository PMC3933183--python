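"""Taxon-coverage decisiveness of the gene x taxon presence pattern.

A coverage pattern is decisive for a tree when every internal edge is
"displayed" by at least one gene: some gene samples at least one taxon in
each of the four subtrees meeting at that edge (equivalently, the gene
contains a quartet crossing the edge).  A pattern decisive for every
binary tree guarantees that per-gene trees can in principle determine a
unique supertree.  The module reports triplet and quadruple taxon
coverage (exact enumeration or Monte-Carlo) together with the per-tree
edge-display test and its all-trees closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import dendropy
import numpy as np

from .types import Alignment, CoverageMatrix, PartitionScheme, PlastidPhyloError

EXACT_TUPLE_LIMIT = 10**9


def coverage_from_matrix(
    matrix: Alignment,
    scheme: PartitionScheme,
    min_present: int = 1,
) -> CoverageMatrix:
    """Derive gene x taxon presence from the supermatrix.

    A taxon "has" a gene iff at least ``min_present`` of the gene's columns
    hold a non-missing character (not '-', '?', 'N'/'X').
    """
    scheme.validate_against(matrix)
    arr = matrix.to_array()
    missing = np.zeros(arr.shape, dtype=bool)
    for ch in "-?NX":
        missing |= arr == ch.encode()
    present_rows = []
    genes = []
    for p in scheme.partitions:
        ok = (~missing[:, p.columns]).sum(axis=1) >= min_present
        present_rows.append(ok)
        genes.append(p.label)
    return CoverageMatrix(
        genes=genes, taxa=list(matrix.taxa),
        present=np.vstack(present_rows),
    )


@dataclass
class DecisivenessReport:
    fraction_triplets: float
    fraction_quadruples: float
    triplets_se: float
    quadruples_se: float
    mode: str  # exact | sampled


def tuple_coverage(
    cov: CoverageMatrix,
    k: int,
    mode: str = "exact",
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Fraction of k-subsets of taxa jointly present in >= 1 gene.

    Returns ``(fraction, standard_error)``; the s.e. is 0 in exact mode
    and the binomial s.e. in sampled mode.
    """
    n = cov.n_taxa
    if k > n:
        raise PlastidPhyloError(f"k={k} exceeds {n} taxa")
    masks = cov.taxon_gene_masks()
    if mode == "exact":
        total = math.comb(n, k)
        if total > EXACT_TUPLE_LIMIT:
            raise PlastidPhyloError(
                f"{total} tuples: exact enumeration infeasible, use sampling"
            )
        covered = 0
        for combo in combinations(range(n), k):
            m = masks[combo[0]]
            for j in combo[1:]:
                m &= masks[j]
                if not m:
                    break
            if m:
                covered += 1
        return covered / total, 0.0
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_samples):
            combo = rng.choice(n, size=k, replace=False)
            m = masks[combo[0]]
            for j in combo[1:]:
                m &= int(masks[j])
                if not m:
                    break
            if m:
                hits += 1
        p = hits / n_samples
        se = math.sqrt(max(p * (1 - p), 1e-12) / n_samples)
        return p, se
    raise PlastidPhyloError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Edge-display (per-tree decisiveness) test
# ---------------------------------------------------------------------------

def _adjacency_from_tree(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Unrooted adjacency map and leaf-name map from a dendropy tree."""
    adj: dict[int, set[int]] = {}
    leaf_name: dict[int, str] = {}
    ids: dict[int, int] = {}

    def nid(nd) -> int:
        key = id(nd)
        if key not in ids:
            ids[key] = len(ids)
            adj[ids[key]] = set()
        return ids[key]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        adj[a].add(b)
        adj[b].add(a)
    for leaf in tree.leaf_node_iter():
        leaf_name[nid(leaf)] = leaf.taxon.label
    # suppress a degree-2 root if present (unrooted interpretation)
    for v in list(adj):
        if len(adj[v]) == 2 and v not in leaf_name:
            u, w = sorted(adj[v])
            adj[u].discard(v)
            adj[w].discard(v)
            adj[u].add(w)
            adj[w].add(u)
            del adj[v]
    return adj, leaf_name


def _subtree_leaves(adj: dict, leaf_name: dict, start: int, blocked: int) -> set[str]:
    """Leaf labels reachable from ``start`` without crossing ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    out: set[str] = set()
    while stack:
        v = stack.pop()
        if v in leaf_name:
            out.add(leaf_name[v])
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return out


def _internal_edge_quadruples(adj: dict, leaf_name: dict):
    """For each internal edge (u, v), the four adjacent subtree leaf sets."""
    for u in adj:
        for v in adj[u]:
            if u >= v or u in leaf_name or v in leaf_name:
                continue
            u_sides = [w for w in adj[u] if w != v]
            v_sides = [w for w in adj[v] if w != u]
            if len(u_sides) != 2 or len(v_sides) != 2:
                raise PlastidPhyloError("tree is not binary")
            yield (
                _subtree_leaves(adj, leaf_name, u_sides[0], u),
                _subtree_leaves(adj, leaf_name, u_sides[1], u),
                _subtree_leaves(adj, leaf_name, v_sides[0], v),
                _subtree_leaves(adj, leaf_name, v_sides[1], v),
            )


def decisive_for_tree(tree: dendropy.Tree, cov: CoverageMatrix) -> bool:
    """True iff every internal edge is displayed by some gene.

    An edge is displayed when a single gene samples at least one taxon in
    each of the four subtrees meeting at that edge.
    """
    adj, leaf_name = _adjacency_from_tree(tree)
    gene_taxa = [
        {cov.taxa[j] for j in np.flatnonzero(cov.present[g])}
        for g in range(cov.n_genes)
    ]
    for quad in _internal_edge_quadruples(adj, leaf_name):
        if not any(all(gt & side for side in quad) for gt in gene_taxa):
            return False
    return True


def _enumerate_topologies(labels: Sequence[str]):
    """All unrooted binary leaf-labelled topologies, as adjacency structures.

    Built by sequential leaf insertion into every edge; yields
    ``(adj, leaf_name)`` pairs ((2n-5)!! of them).
    """
    labels = list(labels)
    if len(labels) < 4:
        raise PlastidPhyloError("need >= 4 taxa to enumerate topologies")

    # edge-list representation: list of (a, b) over integer node ids;
    # leaves are ids 0..n-1 in label order, internal nodes follow.
    def insert(edges, next_id, leaf):
        for i, (a, b) in enumerate(edges):
            new_edges = edges[:i] + edges[i + 1:]
            mid = next_id
            yield new_edges + [(a, mid), (mid, b), (mid, leaf)], next_id + 1

    hub = len(labels)  # internal node ids start after the leaf ids
    states = [([(0, hub), (hub, 1), (hub, 2)], hub + 1)]  # star on 3 leaves
    for leaf in range(3, len(labels)):
        new_states = []
        for edges, next_id in states:
            new_states.extend(insert(edges, next_id, leaf))
        states = new_states
    for edges, _ in states:
        adj: dict[int, set[int]] = {}
        for a, b in edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        leaf_name = {i: labels[i] for i in range(len(labels))}
        yield adj, leaf_name


def random_topology(labels: Sequence[str], rng: np.random.Generator):
    """Uniform random unrooted binary topology by random leaf insertion."""
    labels = list(labels)
    edges = [(0, len(labels)), (len(labels), 1), (len(labels), 2)]
    next_id = len(labels) + 1
    for leaf in range(3, len(labels)):
        i = int(rng.integers(len(edges)))
        a, b = edges.pop(i)
        mid = next_id
        next_id += 1
        edges.extend([(a, mid), (mid, b), (mid, leaf)])
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj, {i: labels[i] for i in range(len(labels))}


def _decisive_adj(adj, leaf_name, gene_taxa) -> bool:
    for quad in _internal_edge_quadruples(adj, leaf_name):
        if not any(all(gt & side for side in quad) for gt in gene_taxa):
            return False
    return True


def decisive_for_all_trees(
    cov: CoverageMatrix,
    n_max_exact: int = 7,
    n_samples: int = 1000,
    seed: Optional[int] = None,
    allow_sampling: bool = False,
) -> tuple[bool, str]:
    """Decisiveness over all binary topologies.

    Exact for <= ``n_max_exact`` taxa (enumerating all (2n-5)!!
    topologies); for larger problems, uniformly sampled topologies give a
    one-sided check (a single failure proves non-decisiveness) when
    ``allow_sampling`` is set.  Returns ``(decisive, mode)``.
    """
    gene_taxa = [
        {cov.taxa[j] for j in np.flatnonzero(cov.present[g])}
        for g in range(cov.n_genes)
    ]
    if cov.n_taxa <= n_max_exact:
        for adj, leaf_name in _enumerate_topologies(cov.taxa):
            if not _decisive_adj(adj, leaf_name, gene_taxa):
                return False, "exact"
        return True, "exact"
    if not allow_sampling:
        raise PlastidPhyloError(
            f"{cov.n_taxa} taxa too many for exact enumeration; "
            "pass allow_sampling=True"
        )
    rng = np.random.default_rng(seed)
    for _ in range(n_samples):
        adj, leaf_name = random_topology(cov.taxa, rng)
        if not _decisive_adj(adj, leaf_name, gene_taxa):
            return False, "sampled"
    return True, "sampled"


def decisiveness_report(
    cov: CoverageMatrix,
    mode: str = "auto",
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> DecisivenessReport:
    """Triplet and quadruple coverage, exact when feasible."""
    if mode == "auto":
        exact_ok = math.comb(cov.n_taxa, 4) <= 5_000_000
        mode = "exact" if exact_ok else "sampled"
    f3, se3 = tuple_coverage(cov, 3, mode=mode, n_samples=n_samples, seed=seed)
    f4, se4 = tuple_coverage(cov, 4, mode=mode, n_samples=n_samples,
                             seed=None if seed is None else seed + 1)
    return DecisivenessReport(
        fraction_triplets=f3, fraction_quadruples=f4,
        triplets_se=se3, quadruples_se=se4, mode=mode,
    )
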