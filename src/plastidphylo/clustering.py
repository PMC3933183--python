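"""Homolog clustering from all-vs-all similarity hits.

Putative single-gene clusters are built by single-linkage clustering of the
significant-hit graph (a sequence joins a cluster if it is connected to it by
a path of significant hits), then refined: clusters holding two or more
distinct sequences from one taxon are re-clustered at successively stricter
e-values; clusters that appear to be fragments of one gene can be merged
using external annotations; inverted-repeat duplicates are collapsed or
dropped; and sparsely sampled clusters are removed by an occupancy filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx

from .types import PlastidPhyloError, SimilarityHit

DEFAULT_MAX_EVALUE = 1.0e-5
DEFAULT_MIN_COV = 0.40
DEFAULT_EVALUE_FLOOR = 1.0e-30


@dataclass
class ClusterSet:
    """Clusters of sequence ids plus a provenance log of refinement actions."""

    clusters: dict[str, list[str]]
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self) -> set[str]:
        out: set[str] = set()
        for ms in self.clusters.values():
            dup = out.intersection(ms)
            if dup:
                raise PlastidPhyloError(f"sequences in multiple clusters: {dup}")
            out.update(ms)
        return out

    def log(self, action: str, **info) -> None:
        self.provenance.append({"action": action, **info})


def default_taxon_of(seq_id: str) -> str:
    """Default seq-id convention: taxon is the part before the first '|'."""
    return seq_id.split("|")[0]


def filter_hits(
    hits: Iterable[SimilarityHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_cov: float = DEFAULT_MIN_COV,
) -> list[tuple[str, str, float]]:
    """Keep significant hits as undirected edges ``(a, b, evalue)``.

    A hit survives iff its e-value is <= ``max_evalue`` and both query and
    target coverage are >= ``min_cov``.  Self-hits are dropped and
    reciprocal duplicates collapsed, keeping the best (smallest) e-value.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.target_id:
            continue
        if h.evalue > max_evalue:
            continue
        if h.query_cov < min_cov or h.target_cov < min_cov:
            continue
        key = tuple(sorted((h.query_id, h.target_id)))
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    return [(a, b, e) for (a, b), e in sorted(best.items())]


def cluster_single_linkage(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str, float]],
    prefix: str = "c",
) -> ClusterSet:
    """Single-linkage clusters = connected components of the hit graph.

    Singletons (nodes without significant hits) are retained as size-1
    clusters.  Cluster ids are assigned deterministically over components
    sorted by their smallest member id.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, _e in edges:
        for n in (a, b):
            if n not in g:
                raise PlastidPhyloError(f"edge endpoint {n!r} not in node set")
        g.add_edge(a, b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    width = max(3, len(str(len(comps))))
    clusters = {f"{prefix}{i + 1:0{width}d}": comp for i, comp in enumerate(comps)}
    return ClusterSet(clusters=clusters)


def multicopy_taxa(
    members: Sequence[str],
    taxon_of: Callable[[str], str] = default_taxon_of,
    sequences: Optional[Mapping[str, str]] = None,
    benign_pairs: Optional[set] = None,
) -> set[str]:
    """Taxa contributing two or more *distinct* genes' worth of sequences.

    A taxon offends (looks like it holds two different genes) when some
    pair of its copies is neither an identical string (``sequences``
    given) nor listed in ``benign_pairs`` (e.g. near-identical
    inverted-repeat copies flagged by a very strong mutual hit).  A taxon
    whose copies are pairwise benign is a plain IR duplicate and is left
    to the duplicate-resolution rule instead.
    """
    by_taxon: dict[str, list[str]] = {}
    for sid in members:
        by_taxon.setdefault(taxon_of(sid), []).append(sid)
    out = set()
    for t, sids in by_taxon.items():
        if len(sids) < 2:
            continue
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                a, b = sids[i], sids[j]
                if benign_pairs and frozenset((a, b)) in benign_pairs:
                    continue
                if sequences is not None and \
                        sequences[a].upper() == sequences[b].upper():
                    continue
                out.add(t)
                break
            if t in out:
                break
    return out


def ir_grade_pairs(
    members: Sequence[str],
    hits: Iterable[SimilarityHit],
    ir_evalue: float = DEFAULT_EVALUE_FLOOR,
    taxon_of: Callable[[str], str] = default_taxon_of,
) -> set:
    """Within-taxon copy pairs linked by a hit at or below ``ir_evalue`` --
    near-identical pairs presumed to be inverted-repeat duplicates rather
    than distinct genes."""
    member_set = set(members)
    out = set()
    for h in hits:
        if h.query_id not in member_set or h.target_id not in member_set:
            continue
        if h.query_id == h.target_id:
            continue
        if taxon_of(h.query_id) == taxon_of(h.target_id) and h.evalue <= ir_evalue:
            out.add(frozenset((h.query_id, h.target_id)))
    return out


def stringency_schedule(
    start: float = DEFAULT_MAX_EVALUE,
    factor: float = 10.0,
    floor: float = DEFAULT_EVALUE_FLOOR,
) -> list[float]:
    """Successively stricter e-value cutoffs: start/factor, ..., down to floor."""
    schedule = []
    e = start / factor
    while e >= floor / (1 + 1e-12):
        schedule.append(e)
        e /= factor
    return schedule


def refine_multicopy(
    cluster_members: Sequence[str],
    hits: Iterable[SimilarityHit],
    schedule: Optional[Sequence[float]] = None,
    min_cov: float = DEFAULT_MIN_COV,
    taxon_of: Callable[[str], str] = default_taxon_of,
    cluster_id: str = "c",
    log: Optional[list] = None,
    sequences: Optional[Mapping[str, str]] = None,
    ir_evalue: float = DEFAULT_EVALUE_FLOOR,
) -> ClusterSet:
    """Re-cluster a multi-copy cluster at successively stricter e-values.

    At each step the within-cluster hit graph is re-filtered at the next
    (stricter) cutoff and re-clustered; sub-clusters that are still
    multi-copy recurse down the remaining schedule.  If the floor is
    reached and a sub-cluster is still multi-copy, the offending taxa's
    sequences are removed from it (conservative fallback: keep the gene,
    lose the taxon) and the removal is logged.
    """
    if schedule is None:
        schedule = stringency_schedule()
    if len(schedule) == 0:
        raise PlastidPhyloError("empty stringency schedule")
    out = ClusterSet(clusters={})
    if log is not None:
        out.provenance = log

    members = set(cluster_members)
    relevant = [h for h in hits
                if h.query_id in members and h.target_id in members]
    benign = ir_grade_pairs(cluster_members, relevant, ir_evalue, taxon_of)

    def recurse(members: list[str], cutoffs: Sequence[float], cid: str) -> None:
        offenders = multicopy_taxa(members, taxon_of, sequences, benign)
        if not offenders:
            out.clusters[cid] = sorted(members)
            return
        if not cutoffs:
            kept = [m for m in members if taxon_of(m) not in offenders]
            out.log("drop_multicopy_taxa", cluster=cid,
                    taxa=sorted(offenders),
                    removed=sorted(set(members) - set(kept)))
            if kept:
                out.clusters[cid] = sorted(kept)
            return
        cutoff = cutoffs[0]
        sub = [h for h in relevant
               if h.query_id in members and h.target_id in members]
        edges = filter_hits(sub, max_evalue=cutoff, min_cov=min_cov)
        comps = cluster_single_linkage(members, edges).clusters
        if len(comps) > 1:
            out.log("recluster", cluster=cid, evalue=cutoff,
                    n_subclusters=len(comps))
        for i, comp in enumerate(comps.values()):
            sub_id = cid if len(comps) == 1 else f"{cid}.{i + 1}"
            recurse(list(comp), cutoffs[1:], sub_id)

    recurse(sorted(members), list(schedule), cluster_id)
    return out


def merge_split_genes(
    clusters: ClusterSet,
    annotations: Optional[Mapping[str, str]] = None,
    taxon_of: Callable[[str], str] = default_taxon_of,
) -> ClusterSet:
    """Merge clusters that are fragments of one annotated gene.

    Clusters whose members' majority annotation label agrees are merged
    only when their taxon sets are pairwise disjoint; overlapping
    candidates are flagged in the provenance log but left unmerged (the
    overlap suggests paralogy rather than a split gene).  With no
    annotations this is the identity.
    """
    if annotations is None:
        return clusters

    def majority_label(members: Sequence[str]) -> Optional[str]:
        counts: dict[str, int] = {}
        for sid in members:
            lab = annotations.get(sid)
            if lab is not None:
                counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            return None
        return max(sorted(counts), key=lambda l: counts[l])

    by_label: dict[str, list[str]] = {}
    for cid, members in clusters.clusters.items():
        lab = majority_label(members)
        if lab is not None:
            by_label.setdefault(lab, []).append(cid)

    out = ClusterSet(clusters=dict(clusters.clusters),
                     provenance=list(clusters.provenance))
    for lab, cids in sorted(by_label.items()):
        if len(cids) < 2:
            continue
        taxa_sets = [
            {taxon_of(s) for s in clusters.clusters[c]} for c in cids
        ]
        disjoint = all(
            taxa_sets[i].isdisjoint(taxa_sets[j])
            for i in range(len(cids)) for j in range(i + 1, len(cids))
        )
        if not disjoint:
            out.log("merge_candidate_overlap", label=lab, clusters=sorted(cids))
            continue
        merged = sorted(m for c in cids for m in clusters.clusters[c])
        keep = min(cids)
        for c in cids:
            del out.clusters[c]
        out.clusters[keep] = merged
        out.log("merged_split_gene", label=lab, clusters=sorted(cids),
                into=keep)
    return out


def resolve_ir_duplicates(
    cluster_members: Sequence[str],
    sequences: Mapping[str, str],
    taxon_of: Callable[[str], str] = default_taxon_of,
    log: Optional[ClusterSet] = None,
    cluster_id: str = "",
) -> list[str]:
    """Resolve within-taxon duplicates (inverted-repeat copies).

    If all of a taxon's copies are identical (exact string equality after
    uppercasing) one is kept; if any pair differs the taxon's sequences are
    all removed from the cluster.  More than two copies are treated the
    same way: identical set -> keep one, otherwise drop all.
    """
    by_taxon: dict[str, list[str]] = {}
    for sid in cluster_members:
        by_taxon.setdefault(taxon_of(sid), []).append(sid)
    kept: list[str] = []
    for taxon in sorted(by_taxon):
        sids = sorted(by_taxon[taxon])
        if len(sids) == 1:
            kept.append(sids[0])
            continue
        seqs = {sequences[s].upper() for s in sids}
        if len(seqs) == 1:
            kept.append(sids[0])
            if log is not None:
                log.log("ir_duplicate_kept_one", cluster=cluster_id,
                        taxon=taxon, kept=sids[0], dropped=sids[1:])
        else:
            if log is not None:
                log.log("ir_duplicate_divergent_dropped", cluster=cluster_id,
                        taxon=taxon, removed=sids)
    return kept


def occupancy_filter(
    clusters: ClusterSet,
    n_taxa: int,
    min_frac: float = 0.5,
    taxon_of: Callable[[str], str] = default_taxon_of,
) -> ClusterSet:
    """Keep clusters whose distinct-taxon count is >= ceil(min_frac * n_taxa).

    With the default 0.5 a cluster holding exactly half the taxa qualifies
    ("at least 50%" occupancy).
    """
    if n_taxa <= 0:
        raise PlastidPhyloError(f"n_taxa must be positive, got {n_taxa}")
    threshold = math.ceil(min_frac * n_taxa)
    out = ClusterSet(clusters={}, provenance=list(clusters.provenance))
    for cid in sorted(clusters.clusters):
        members = clusters.clusters[cid]
        n = len({taxon_of(s) for s in members})
        if n >= threshold:
            out.clusters[cid] = list(members)
        else:
            out.log("occupancy_dropped", cluster=cid, n_taxa=n,
                    threshold=threshold)
    return out


def cluster_pipeline(
    hits: Sequence[SimilarityHit],
    seq_ids: Sequence[str],
    sequences: Optional[Mapping[str, str]] = None,
    n_taxa: Optional[int] = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_cov: float = DEFAULT_MIN_COV,
    min_occupancy: float = 0.5,
    annotations: Optional[Mapping[str, str]] = None,
    schedule: Optional[Sequence[float]] = None,
    taxon_of: Callable[[str], str] = default_taxon_of,
) -> ClusterSet:
    """Full clustering stage: filter -> single-linkage -> stringency
    refinement -> split-gene merge -> IR-duplicate resolution -> occupancy
    filter."""
    edges = filter_hits(hits, max_evalue=max_evalue, min_cov=min_cov)
    initial = cluster_single_linkage(seq_ids, edges)
    refined = ClusterSet(clusters={}, provenance=initial.provenance)
    for cid in sorted(initial.clusters):
        members = initial.clusters[cid]
        if multicopy_taxa(members, taxon_of, sequences):
            sub = refine_multicopy(
                members, hits, schedule=schedule, min_cov=min_cov,
                taxon_of=taxon_of, cluster_id=cid, log=refined.provenance,
                sequences=sequences,
            )
            refined.clusters.update(sub.clusters)
        else:
            refined.clusters[cid] = list(members)
    merged = merge_split_genes(refined, annotations, taxon_of)
    if sequences is not None:
        resolved = ClusterSet(clusters={}, provenance=merged.provenance)
        for cid in sorted(merged.clusters):
            kept = resolve_ir_duplicates(
                merged.clusters[cid], sequences, taxon_of,
                log=resolved, cluster_id=cid,
            )
            if kept:
                resolved.clusters[cid] = kept
        merged = resolved
    if n_taxa is None:
        n_taxa = len({taxon_of(s) for s in seq_ids})
    return occupancy_filter(merged, n_taxa, min_occupancy, taxon_of)
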