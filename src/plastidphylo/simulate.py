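"""Synthetic plastome-like data with controlled statistical structure.

The generator produces everything the pipeline consumes without any
downloads: a birth-process tree, per-gene codon alignments with
position-specific rates and lineage-heterogeneous GC content, gene-wise
missingness, inverted-repeat duplicates, paralogs, and an all-vs-all
similarity hit table with known truth labels.

GC heterogeneity is simulated with a layered construction that makes
RY-coding exactly neutral: a shared binary purine/pyrimidine (R/Y) chain
evolves along the tree, and two independent *subtype* chains decide which
purine (A vs G) and which pyrimidine (T vs C) is realised at every node.
Branch-specific GC shifts act only on the subtype equilibria (within-class
A<->G / C<->T exchanges), so re-running with different shift targets but
the same seed changes the nucleotide matrix while leaving its RY-coded
projection byte-identical -- which is precisely the argument for RY-coding
as a response to compositional bias.

Simulated "e-values" are labels for threshold rehearsal, not statistical
e-values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .substmodels import SubstitutionModel, discrete_gamma, eigen_decompose
from .types import (
    Alignment,
    CoverageMatrix,
    PlastidPhyloError,
    SequenceRecord,
    SimilarityHit,
)
from .build import translate_cds

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic plastome data set.

    Defaults are a desk-scale rendering of a 360-taxon, 78-gene plastome
    matrix: 40 taxa, 12 protein-coding genes averaging ~249 codons,
    occupancy drawn so that global missingness lands near 15.6%, third
    codon positions evolving fastest and carrying nearly all of the
    lineage GC heterogeneity.
    """

    n_taxa: int = 40
    n_genes: int = 12
    codon_mean: float = 249.0
    codon_sd: float = 60.0
    codon_min: int = 60
    birth_rate: float = 1.0
    mean_branch_length: float = 0.08
    base_freqs: tuple = (0.31, 0.18, 0.21, 0.30)  # A C G T; GC = 0.39
    position_rates: tuple = (1.0, 0.5, 2.5)
    within_class_factor: float = 2.0  # transition-like excess
    site_rate_alpha: float = 0.8     # gamma rate variation across codons
    gene_rate_sigma: float = 0.4     # lognormal sd of per-gene rate multipliers
    gene_gc_jitter: float = 0.06     # sd of per-gene subtype-equilibrium shifts
    n_shifted_clades: int = 2
    gc3_targets: tuple = (0.15, 0.70)
    gc12_shift_weight: float = 0.3   # positions 1-2 move this fraction of the way
    occupancy_beta: tuple = (5.5, 2.5)  # scaled to [0.5, 1]; mean ~0.844
    min_occupancy: float = 0.5
    ir_dup_rate: float = 0.25
    ir_divergence_rate: float = 0.1
    paralog_rate: float = 0.1
    paralog_taxon_frac: float = 0.55
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0


def sample_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    mean_branch_length: float = 0.08,
    seed: int = 0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree, edge lengths rescaled to the requested mean.

    Leaves are labelled ``t001``..; fully deterministic given the seed.
    """
    if n_taxa < 3:
        raise PlastidPhyloError("need at least 3 taxa")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_taxa, rng=rng,
    )
    width = max(3, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:0{width}d}"
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length]
    mean = sum(lengths) / len(lengths)
    scale = mean_branch_length / mean
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Layered gene simulation
# ---------------------------------------------------------------------------

@dataclass
class GcShift:
    """A clade-specific GC target: subtype equilibria inside the clade move
    to ``targets[pos]`` (the clade's stem edge re-equilibrates fully)."""

    clade: frozenset  # leaf labels
    targets: dict     # position (1..3) -> GC fraction target


def _node_shift_info(tree: dendropy.Tree, shifts: Sequence[GcShift]):
    """Per-node (targets, is_stem) derived from clade definitions."""
    info = {}
    for nd in tree.preorder_node_iter():
        leafset = frozenset(l.taxon.label for l in nd.leaf_iter())
        for sh in shifts:
            if leafset <= sh.clade:
                info[id(nd)] = (sh.targets, leafset == sh.clade)
                break
    return info


def simulate_gene(
    tree: dendropy.Tree,
    n_codons: int,
    config: SimConfig,
    shifts: Sequence[GcShift] = (),
    seed: int = 0,
    rate_multiplier: float = 1.0,
    subtype_eq: Optional[tuple[float, float]] = None,
) -> dict[str, str]:
    """Simulate one gap-free, aligned CDS per taxon.

    Codon positions evolve at ``position_rates``; per-codon rates are
    gamma-distributed; GC shifts act on subtype equilibria only (see
    module docstring).  Internal stop codons at the leaves are repaired to
    tryptophan (TGG) by within-purine edits, which preserves the RY layer.
    """
    ss = np.random.SeedSequence(seed)
    rng_site, rng_class, rng_sub = [np.random.default_rng(c) for c in ss.spawn(3)]

    piA, piC, piG, piT = config.base_freqs
    pi_r, pi_y = piA + piG, piC + piT
    if subtype_eq is None:
        g0, c0 = piG / pi_r, piC / pi_y  # subtype equilibria (G|R, C|Y)
    else:
        g0, c0 = subtype_eq

    L = 3 * n_codons
    pos = np.tile([1, 2, 3], n_codons)
    pos_rate = np.asarray(config.position_rates)[pos - 1]
    codon_rate = rng_site.gamma(config.site_rate_alpha,
                                1.0 / config.site_rate_alpha, size=n_codons)
    site_rate = np.repeat(codon_rate, 3) * pos_rate * rate_multiplier
    between = site_rate                      # class-switch intensity
    within = site_rate * config.within_class_factor

    shift_info = _node_shift_info(tree, shifts)

    def shifted_eq(nd) -> tuple[np.ndarray, bool]:
        """Per-column subtype equilibrium for the edge leading to nd."""
        entry = shift_info.get(id(nd))
        if entry is None:
            return None, False
        targets, is_stem = entry
        eq = np.where(pos == 1, targets.get(1, g0), 0.0)
        eq = np.where(pos == 2, targets.get(2, g0), eq)
        eq = np.where(pos == 3, targets.get(3, g0), eq)
        return eq, is_stem

    # chain states per node: class (1 = Y), purine subtype (1 = G),
    # pyrimidine subtype (1 = C)
    root = tree.seed_node
    states = {}
    states[id(root)] = (
        (rng_class.random(L) < pi_y).astype(np.int8),
        (rng_sub.random(L) < g0).astype(np.int8),
        (rng_sub.random(L) < c0).astype(np.int8),
    )
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length or 0.0
        p_cls, p_pur, p_pyr = states[id(nd.parent_node)]
        # class layer: 2-state chain with equilibrium pi_y
        decay = np.exp(-between * t / (2.0 * pi_r * pi_y))
        p_y = pi_y + (p_cls - pi_y) * decay
        cls = (rng_class.random(L) < p_y).astype(np.int8)
        # subtype layers: branch-specific equilibria under GC shifts
        eq, is_stem = shifted_eq(nd)
        g_eq = np.full(L, g0) if eq is None else eq
        c_eq = np.full(L, c0) if eq is None else eq
        decay_w = 0.0 if is_stem else np.exp(-within * t)
        pg = g_eq + (p_pur - g_eq) * decay_w
        pc = c_eq + (p_pyr - c_eq) * decay_w
        pur = (rng_sub.random(L) < pg).astype(np.int8)
        pyr = (rng_sub.random(L) < pc).astype(np.int8)
        states[id(nd)] = (cls, pur, pyr)

    bases = np.array([b"A", b"G", b"T", b"C"])  # indexed 2*cls + subtype
    out = {}
    for leaf in tree.leaf_node_iter():
        cls, pur, pyr = states[id(leaf)]
        subtype = np.where(cls == 0, pur, pyr)
        seq = bases[2 * cls + subtype].tobytes().decode("ascii")
        out[leaf.taxon.label] = _repair_stops(seq)
    return out


def _repair_stops(cds: str) -> str:
    """Remove stop codons by within-pyrimidine edits, composition-balanced.

    Each stop (TAA/TAG/TGA) becomes CAA/CAG/CGA (T->C at position 1, a
    within-class flip so the RY layer is untouched); to keep base
    composition unbiased, an equal number of other codons with C at
    position 1 are flipped back C->T (skipping any flip that would create
    a stop, which also protects the just-repaired codons).
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    debt = 0
    for i, c in enumerate(codons):
        if c in _STOPS:
            codons[i] = "C" + c[1:]
            debt += 1
    if debt:
        for i, c in enumerate(codons):
            if debt == 0:
                break
            if c[0] == "C" and ("T" + c[1:]) not in _STOPS:
                codons[i] = "T" + c[1:]
                debt -= 1
    return "".join(codons)


def choose_shift_clades(
    tree: dendropy.Tree, config: SimConfig, seed: int = 0
) -> list[GcShift]:
    """Pick non-overlapping clades (10-40% of taxa) and assign GC targets."""
    rng = np.random.default_rng(seed)
    n = sum(1 for _ in tree.leaf_node_iter())
    candidates = []
    for nd in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 0.1 * n <= len(leaves) <= 0.4 * n:
            candidates.append(leaves)
    shifts: list[GcShift] = []
    order = rng.permutation(len(candidates))
    base_gc = config.base_freqs[1] + config.base_freqs[2]
    for idx in order:
        if len(shifts) >= config.n_shifted_clades:
            break
        clade = candidates[idx]
        if any(clade & s.clade for s in shifts):
            continue
        t3 = config.gc3_targets[len(shifts) % len(config.gc3_targets)]
        t12 = base_gc + config.gc12_shift_weight * (t3 - base_gc)
        shifts.append(GcShift(clade=clade, targets={1: t12, 2: t12, 3: t3}))
    return shifts


# ---------------------------------------------------------------------------
# Missingness, duplicates, paralogs, hit table
# ---------------------------------------------------------------------------

def apply_missingness(
    genes: Mapping[str, Mapping[str, str]],
    config: SimConfig,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], CoverageMatrix]:
    """Delete taxa per gene according to the occupancy distribution.

    Occupancy per gene is ``min_occupancy + (1-min_occupancy) * Beta(a, b)``
    (defaults tuned so global missingness is near 15.6%); the returned
    coverage matrix is the ground truth of what remains.
    """
    rng = np.random.default_rng(seed)
    gene_names = sorted(genes)
    taxa = sorted({t for g in genes.values() for t in g})
    n = len(taxa)
    out: dict[str, dict[str, str]] = {}
    present = np.zeros((len(gene_names), n), dtype=bool)
    a, b = config.occupancy_beta
    for gi, gene in enumerate(gene_names):
        occ = config.min_occupancy + (1 - config.min_occupancy) * rng.beta(a, b)
        keep_n = max(int(np.ceil(config.min_occupancy * n)), round(occ * n))
        kept = set(np.array(taxa)[rng.choice(n, size=min(keep_n, n),
                                             replace=False)])
        out[gene] = {t: s for t, s in genes[gene].items() if t in kept}
        for t in out[gene]:
            present[gi, taxa.index(t)] = True
    cov = CoverageMatrix(genes=gene_names, taxa=taxa, present=present)
    return out, cov


def _mutate_within_class(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Apply within-class point flips (A<->G, C<->T) avoiding stop codons."""
    flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
    chars = list(seq)
    done = 0
    guard = 0
    while done < n_mut and guard < 100 * n_mut + 100:
        guard += 1
        i = int(rng.integers(len(chars)))
        old = chars[i]
        chars[i] = flip[old]
        codon_start = 3 * (i // 3)
        codon = "".join(chars[codon_start:codon_start + 3])
        if codon in _STOPS:
            chars[i] = old
            continue
        done += 1
    return "".join(chars)


@dataclass
class SimTruth:
    """Truth labels: seq_id -> gene, copy tags, paralog pairs."""

    gene_of: dict[str, str]
    copy_tag: dict[str, str]            # primary | ir | paralog
    paralog_pairs: set                  # frozensets of related gene labels
    divergent_ir: set                   # seq ids whose IR copy differs


def inject_duplicates_and_paralogs(
    genes: Mapping[str, Mapping[str, str]],
    config: SimConfig,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], SimTruth]:
    """Add inverted-repeat duplicates and paralogous gene copies.

    Output maps gene label -> {seq_id: cds}; seq ids follow the
    ``taxon|tag`` convention.  IR copies are exact duplicates except for a
    configurable fraction that receive one within-class point mutation
    (rehearsing the "identical -> keep one, different -> drop both" rule).
    Paralogs are diverged copies for a taxon subset, labelled as their own
    gene.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    truth = SimTruth(gene_of={}, copy_tag={}, paralog_pairs=set(),
                     divergent_ir=set())
    for gene in sorted(genes):
        members = genes[gene]
        gmap: dict[str, str] = {}
        for taxon in sorted(members):
            sid = f"{taxon}|{gene}"
            gmap[sid] = members[taxon]
            truth.gene_of[sid] = gene
            truth.copy_tag[sid] = "primary"
        is_ir = rng.random() < config.ir_dup_rate
        if is_ir:
            for taxon in sorted(members):
                sid = f"{taxon}|{gene}_ir"
                seq = members[taxon]
                if rng.random() < config.ir_divergence_rate:
                    seq = _mutate_within_class(seq, 1, rng)
                    truth.divergent_ir.add(sid)
                gmap[sid] = seq
                truth.gene_of[sid] = gene
                truth.copy_tag[sid] = "ir"
        out[gene] = gmap
        if rng.random() < config.paralog_rate:
            pgene = f"{gene}p"
            taxa = sorted(members)
            k = max(2, round(config.paralog_taxon_frac * len(taxa)))
            chosen = [taxa[i] for i in rng.choice(len(taxa), size=min(k, len(taxa)),
                                                  replace=False)]
            pmap: dict[str, str] = {}
            for taxon in sorted(chosen):
                sid = f"{taxon}|{pgene}"
                n_mut = max(1, int(0.15 * len(members[taxon])))
                pmap[sid] = _mutate_within_class(members[taxon], n_mut, rng)
                truth.gene_of[sid] = pgene
                truth.copy_tag[sid] = "paralog"
            out[pgene] = pmap
            truth.paralog_pairs.add(frozenset({gene, pgene}))
    return out, truth


def make_hit_table(
    aa_lengths: Mapping[str, int],
    truth: SimTruth,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> list[SimilarityHit]:
    """All-vs-all hit table consistent with the truth labels.

    Within-gene pairs get strong hits (e-value 1e-25..1e-15, coverage
    >= 0.9) minus a false-negative fraction; within-taxon duplicate pairs
    get near-zero e-values (1e-180) so they read as inverted-repeat
    copies; paralogous cross-gene pairs get e-values in (1e-6, 1e-5],
    passing the default filter but separable at one stringency step; and
    spurious cross-gene hits appear at ``fp_rate`` with e-values in
    (1e-5, 1e-3] so the default filter removes them.
    """
    if not (0 <= fp_rate < 1 and 0 <= fn_rate <= 1):
        raise PlastidPhyloError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = sorted(truth.gene_of)
    hits: list[SimilarityHit] = []

    def taxon(sid: str) -> str:
        return sid.split("|")[0]

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ga, gb = truth.gene_of[a], truth.gene_of[b]
            if ga == gb:
                if taxon(a) == taxon(b):
                    ev, cov = 1e-180, 1.0
                else:
                    if rng.random() < fn_rate:
                        continue
                    ev = 10.0 ** -rng.uniform(15, 25)
                    cov = 0.9 + 0.1 * rng.random()
            elif frozenset({ga, gb}) in truth.paralog_pairs:
                ev = 10.0 ** -rng.uniform(5.05, 6.0)
                cov = 0.9
            else:
                if rng.random() >= fp_rate:
                    continue
                ev = 10.0 ** -rng.uniform(3.0, 4.95)
                cov = 0.5 + 0.4 * rng.random()
            hits.append(
                SimilarityHit(query_id=a, target_id=b, evalue=ev,
                              query_cov=cov, target_cov=cov,
                              bitscore=-np.log10(ev + 1e-300))
            )
    return hits


# ---------------------------------------------------------------------------
# Whole-dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    config: SimConfig
    tree: dendropy.Tree
    shifts: list
    genes_clean: dict          # gene -> {taxon: cds} pre-missingness
    genes: dict                # gene -> {seq_id: cds} final (with copies)
    coverage: CoverageMatrix   # primary-copy presence after missingness
    truth: SimTruth
    hits: list
    nt_records: list = field(default_factory=list)
    aa_records: list = field(default_factory=list)

    def cds_by_seq_id(self) -> dict[str, str]:
        return {sid: seq for g in self.genes.values() for sid, seq in g.items()}

    def aligned_matrix(self) -> Alignment:
        """Concatenated primary-copy supermatrix (ground truth, gap-filled)."""
        from .build import GeneAlignment, concatenate

        gene_alns = []
        for gi, gene in enumerate(self.coverage.genes):
            members = {
                t: self.genes_clean[gene][t]
                for t, ok in zip(self.coverage.taxa, self.coverage.present[gi])
                if ok
            }
            taxa = sorted(members)
            nt = Alignment(
                taxa, [members[t] for t in taxa], "nt",
                codon_phase=np.tile([1, 2, 3], len(members[taxa[0]]) // 3),
            )
            aa = Alignment(taxa, [translate_cds(members[t]) for t in taxa], "aa")
            gene_alns.append(
                GeneAlignment(gene_id=gene, aa_alignment=aa, nt_alignment=nt,
                              trim_mask=np.arange(aa.n_columns))
            )
        matrix, _scheme = concatenate(gene_alns, taxa=self.coverage.taxa)
        return matrix


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full synthetic data set; byte-deterministic given the
    config (including its seed)."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(7 + config.n_genes) % (2**31)
    tree = sample_tree(config.n_taxa, config.birth_rate,
                       config.mean_branch_length, seed=int(seeds[0]))
    shifts = (
        choose_shift_clades(tree, config, seed=int(seeds[1]))
        if config.n_shifted_clades > 0 else []
    )
    rng_len = np.random.default_rng(int(seeds[2]))
    codon_counts = np.maximum(
        config.codon_min,
        np.round(rng_len.normal(config.codon_mean, config.codon_sd,
                                size=config.n_genes)).astype(int),
    )
    # per-gene heterogeneity: rate multipliers and subtype-equilibrium
    # jitter (plastid genes differ in both speed and composition)
    rng_gene = np.random.default_rng(int(seeds[6]))
    rate_mults = np.exp(rng_gene.normal(0.0, config.gene_rate_sigma,
                                        size=config.n_genes))
    piA, piC, piG, piT = config.base_freqs
    g_base, c_base = piG / (piA + piG), piC / (piC + piT)
    g_jit = np.clip(g_base + rng_gene.normal(0, config.gene_gc_jitter,
                                             config.n_genes), 0.05, 0.95)
    c_jit = np.clip(c_base + rng_gene.normal(0, config.gene_gc_jitter,
                                             config.n_genes), 0.05, 0.95)
    width = max(2, len(str(config.n_genes)))
    genes_clean = {}
    for gi in range(config.n_genes):
        gene = f"g{gi + 1:0{width}d}"
        genes_clean[gene] = simulate_gene(
            tree, int(codon_counts[gi]), config, shifts,
            seed=int(seeds[7 + gi]),
            rate_multiplier=float(rate_mults[gi]),
            subtype_eq=(float(g_jit[gi]), float(c_jit[gi])),
        )
    pruned, coverage = apply_missingness(genes_clean, config,
                                         seed=int(seeds[3]))
    genes, truth = inject_duplicates_and_paralogs(pruned, config,
                                                  seed=int(seeds[4]))
    nt_records, aa_records = [], []
    aa_lengths = {}
    for gene in sorted(genes):
        for sid in sorted(genes[gene]):
            taxon, tag = sid.split("|", 1)
            cds = genes[gene][sid]
            aa = translate_cds(cds)
            nt_records.append(SequenceRecord(taxon, tag, cds, "nt"))
            aa_records.append(SequenceRecord(taxon, tag, aa, "aa"))
            aa_lengths[sid] = len(aa)
    hits = make_hit_table(aa_lengths, truth, config.fp_rate, config.fn_rate,
                          seed=int(seeds[5]))
    return SimDataset(
        config=config, tree=tree, shifts=shifts, genes_clean=genes_clean,
        genes=genes, coverage=coverage, truth=truth, hits=hits,
        nt_records=nt_records, aa_records=aa_records,
    )


def expected_retained_clusters(
    ds: SimDataset, min_occupancy: float = 0.5
) -> dict[str, set]:
    """Truth-derived expectation of the clusters the pipeline should keep.

    Applies the published filtering rules to the truth labels by set
    arithmetic: identical within-taxon duplicates collapse to the
    first-sorted id, divergent duplicates remove the taxon, and gene
    groups below the occupancy threshold disappear.
    """
    import math

    kept_groups: dict[str, set] = {}
    for gene, members in ds.genes.items():
        by_taxon: dict[str, list[str]] = {}
        for sid in members:
            by_taxon.setdefault(sid.split("|")[0], []).append(sid)
        kept: set = set()
        for taxon, sids in sorted(by_taxon.items()):
            if len(sids) == 1:
                kept.add(sids[0])
            elif len({members[s] for s in sids}) == 1:
                kept.add(sorted(sids)[0])
            # divergent duplicates: taxon dropped from the gene
        if kept:
            kept_groups[gene] = kept
    n_taxa = ds.config.n_taxa
    threshold = math.ceil(min_occupancy * n_taxa)
    return {
        g: v for g, v in kept_groups.items()
        if len({s.split("|")[0] for s in v}) >= threshold
    }


# ---------------------------------------------------------------------------
# Plain GTR+G simulation (used for likelihood calibration and power tests)
# ---------------------------------------------------------------------------

def simulate_gtr_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int = 0,
    states: Optional[str] = None,
) -> Alignment:
    """Simulate an alignment under a plain reversible model with discrete-
    gamma rates (the same process the likelihood engine assumes)."""
    from .likelihood import _FAMILY_STATES

    rng = np.random.default_rng(seed)
    state_chars = states or _FAMILY_STATES[model.family]
    n_states = model.n_states
    eig = eigen_decompose(model)
    rates, probs = discrete_gamma(model.alpha, model.ncat)
    site_cat = rng.choice(len(rates), size=n_sites, p=probs)
    site_rate = rates[site_cat]

    root = tree.seed_node
    seqs = {id(root): rng.choice(n_states, size=n_sites, p=model.freqs)}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length or 0.0
        parent = seqs[id(nd.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for r in np.unique(site_rate):
            p = eig.transition_matrix(t * r)
            p = p / p.sum(axis=1, keepdims=True)
            idx = site_rate == r
            u = rng.random(idx.sum())
            cum = np.cumsum(p[parent[idx]], axis=1)
            child[idx] = (u[:, None] > cum).sum(axis=1)
        seqs[id(nd)] = child
    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append("".join(state_chars[i] for i in seqs[id(leaf)]))
    alphabet = {4: "nt", 2: "ry", 20: "aa"}[n_states]
    return Alignment(taxa, rows, alphabet)
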