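"""End-to-end orchestration: hits -> clusters -> supermatrix -> codings ->
diagnostics -> model selection -> decisiveness, with a hashed run manifest.

Each stage writes plain-text artifacts into the run directory; the manifest
records the configuration echo, per-stage timings and SHA-256 hashes of
every output, so an unchanged rerun reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .build import GeneAlignment, build_gene_alignment, concatenate, remove_taxa
from .clustering import cluster_pipeline, default_taxon_of
from .coding import CODINGS, codon_scheme, derive_coding, single_partition_scheme
from .composition import aa_class_fractions, composition_summary, ols_fit
from .decisiveness import (
    coverage_from_matrix,
    decisive_for_tree,
    decisiveness_report,
)
from .io import (
    write_cluster_table,
    write_coverage_tsv,
    write_hit_table,
    write_newick,
    write_partition_file,
    write_sequences,
    write_supermatrix,
)
from .likelihood import compare_schemes, evaluate_scheme
from .simulate import SimConfig, simulate_dataset
from .types import Alignment, PlastidPhyloError


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-data run."""

    sim: SimConfig = field(default_factory=SimConfig)
    gap_frac: float = 0.5
    genetic_code: int = 11
    min_occupancy: float = 0.5
    codings: tuple = ("ntAll", "ntNo3rd", "nt3rdOnly", "RY", "AA")
    modelsel_schemes: tuple = ("onepart", "codon", "gene", "codongene")
    modelsel_enabled: bool = True
    modelsel_max_rounds: int = 2
    modelsel_rate_multipliers: bool = True
    remove_taxa_list: tuple = ()
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)
    hashes: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: Sequence[str]) -> None:
        entry = {"stage": stage, "seconds": round(seconds, 3),
                 "outputs": list(outputs)}
        self.stages.append(entry)
        for path in outputs:
            with open(path, "rb") as fh:
                self.hashes[os.path.basename(path)] = hashlib.sha256(
                    fh.read()
                ).hexdigest()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "version": self.version,
                 "stages": self.stages, "hashes": self.hashes},
                fh, indent=2, default=str,
            )


class PipelineRun:
    """Holds the in-memory products of a pipeline execution."""

    def __init__(self, out_dir: str, config: PipelineConfig) -> None:
        self.out_dir = out_dir
        self.config = config
        self.manifest = RunManifest(config=config.to_dict(), version=__version__)
        self.matrices: dict[str, Alignment] = {}
        self.schemes: dict = {}
        self.dataset = None
        self.clusters = None
        self.modelsel_table: Optional[pd.DataFrame] = None
        self.diagnostics: Optional[pd.DataFrame] = None
        self.decisiveness = None

    def path(self, name: str) -> str:
        return os.path.join(self.out_dir, name)


def run_pipeline(config: PipelineConfig, out_dir: str) -> PipelineRun:
    """Execute all stages on a simulated data set."""
    os.makedirs(out_dir, exist_ok=True)
    run = PipelineRun(out_dir, config)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    ds = simulate_dataset(config.sim)
    run.dataset = ds
    aa_path = run.path("genes_aa.fasta")
    nt_path = run.path("genes_nt.fasta")
    write_sequences(ds.aa_records, aa_path)
    write_sequences(ds.nt_records, nt_path)
    hits_path = run.path("hits.tsv")
    aa_lengths = {r.seq_id: len(r.seq) for r in ds.aa_records}
    write_hit_table(ds.hits, aa_lengths, hits_path)
    tree_path = run.path("true_tree.nwk")
    write_newick(ds.tree, tree_path)
    cov_path = run.path("coverage_truth.tsv")
    write_coverage_tsv(ds.coverage, cov_path)
    run.manifest.record("simulate", time.perf_counter() - t0,
                        [aa_path, nt_path, hits_path, tree_path, cov_path])

    # --- cluster ------------------------------------------------------
    t0 = time.perf_counter()
    seq_ids = sorted(aa_lengths)
    # duplicate-identity checks use the nucleotide CDS: synonymous changes
    # between inverted-repeat copies still count as "differing slightly"
    nt_seq = {r.seq_id: r.seq for r in ds.nt_records}
    clusters = cluster_pipeline(
        ds.hits, seq_ids, sequences=nt_seq,
        n_taxa=config.sim.n_taxa, min_occupancy=config.min_occupancy,
    )
    run.clusters = clusters
    clus_path = run.path("clusters.tsv")
    write_cluster_table(clusters.clusters,
                        {s: default_taxon_of(s) for s in aa_lengths},
                        clus_path)
    prov_path = run.path("cluster_provenance.jsonl")
    with open(prov_path, "w") as fh:
        for entry in clusters.provenance:
            fh.write(json.dumps(entry, default=str) + "\n")
    run.manifest.record("cluster", time.perf_counter() - t0,
                        [clus_path, prov_path])

    # --- build supermatrix -------------------------------------------
    t0 = time.perf_counter()
    cds_by_sid = ds.cds_by_seq_id()
    gene_alns: list[GeneAlignment] = []
    for cid in sorted(clusters.clusters):
        members = sorted(clusters.clusters[cid])
        taxa = [default_taxon_of(s) for s in members]
        from .build import translate_cds

        aa_rows = [translate_cds(cds_by_sid[s], code=config.genetic_code)
                   for s in members]
        aa_aln = Alignment(taxa, aa_rows, "aa")
        cds_map = {t: cds_by_sid[s] for t, s in zip(taxa, members)}
        gene_alns.append(
            build_gene_alignment(cid, aa_aln, cds_map,
                                 max_gap_frac=config.gap_frac,
                                 code=config.genetic_code)
        )
    matrix, gene_scheme = concatenate(gene_alns)
    run.matrices["ntAll"] = matrix
    run.schemes["gene"] = gene_scheme
    paths = write_supermatrix(matrix, gene_scheme, out_dir, prefix="ntAll")
    run.manifest.record("build", time.perf_counter() - t0,
                        list(paths.values()))

    # --- codings ------------------------------------------------------
    t0 = time.perf_counter()
    outputs = []
    for name in config.codings:
        if name == "ntAll":
            continue
        coded, coded_scheme = derive_coding(matrix, CODINGS[name], gene_scheme,
                                            code=config.genetic_code)
        run.matrices[name] = coded
        p = write_supermatrix(coded, coded_scheme, out_dir, prefix=name)
        outputs.extend(p.values())
    run.manifest.record("recode", time.perf_counter() - t0, outputs)

    # --- composition diagnostics -------------------------------------
    t0 = time.perf_counter()
    diag = composition_summary(matrix)
    run.diagnostics = diag
    diag_path = run.path("composition_tests.tsv")
    diag.to_csv(diag_path, sep="\t", index=False)
    outputs = [diag_path]
    if "AA" in run.matrices:
        from .composition import composition_table

        gc = composition_table(matrix, "all").gc
        fr = aa_class_fractions(run.matrices["AA"]).dropna()
        common = [t for t in fr.index if t in gc.index]
        reg = {}
        for col in ("gc_rich_frac", "at_rich_frac"):
            fit = ols_fit(gc.loc[common].to_numpy(), fr.loc[common, col].to_numpy())
            reg[col] = dataclasses.asdict(fit)
        reg_path = run.path("gc_aa_regressions.json")
        with open(reg_path, "w") as fh:
            json.dump(reg, fh, indent=2)
        outputs.append(reg_path)
    run.manifest.record("diagnose", time.perf_counter() - t0, outputs)

    # --- model selection ---------------------------------------------
    if config.modelsel_enabled:
        t0 = time.perf_counter()
        phase = matrix.codon_phase
        candidates = {
            "onepart": single_partition_scheme(matrix.n_columns, name="onepart"),
            "codon": codon_scheme(gene_scheme, phase, by_gene=False),
            "gene": gene_scheme,
            "codongene": codon_scheme(gene_scheme, phase, by_gene=True),
        }
        results = []
        for sname in config.modelsel_schemes:
            scheme = candidates[sname]
            results.append(
                evaluate_scheme(
                    ds.tree, matrix, scheme,
                    max_rounds=config.modelsel_max_rounds,
                    optimize_rates=config.modelsel_rate_multipliers,
                )
            )
        table = compare_schemes(results)
        run.modelsel_table = table
        ms_path = run.path("model_selection.tsv")
        table.to_csv(ms_path, sep="\t", index=False)
        run.manifest.record("modelsel", time.perf_counter() - t0, [ms_path])

    # --- decisiveness -------------------------------------------------
    t0 = time.perf_counter()
    cov = coverage_from_matrix(matrix, gene_scheme)
    report = decisiveness_report(cov, seed=config.seed)
    run.decisiveness = report
    dec = dataclasses.asdict(report)
    dec["decisive_for_true_tree"] = bool(decisive_for_tree(ds.tree, cov))
    dec_path = run.path("decisiveness.json")
    with open(dec_path, "w") as fh:
        json.dump(dec, fh, indent=2)
    run.manifest.record("decisive", time.perf_counter() - t0, [dec_path])

    # --- taxon-removal sensitivity -----------------------------------
    if config.remove_taxa_list:
        t0 = time.perf_counter()
        reduced = remove_taxa(matrix, list(config.remove_taxa_list))
        run.matrices["ntAll_reduced"] = reduced
        p = write_supermatrix(reduced, gene_scheme, out_dir,
                              prefix="ntAll_reduced")
        run.manifest.record("remove_taxa", time.perf_counter() - t0,
                            list(p.values()))

    run.manifest.write(run.path("manifest.json"))
    return run


def report(run: PipelineRun) -> str:
    """Human-readable summary of a completed run."""
    if run.dataset is None:
        raise PlastidPhyloError("empty run")
    lines = []
    cfg = run.config
    lines.append(f"plastidphylo {__version__} run summary")
    lines.append(f"taxa: {cfg.sim.n_taxa}  genes simulated: {cfg.sim.n_genes}")
    if run.clusters is not None:
        lines.append(f"clusters retained: {run.clusters.n_clusters}")
    for name, m in run.matrices.items():
        lines.append(
            f"matrix {name}: {m.n_taxa} x {m.n_columns} "
            f"({m.alphabet}), missing {100 * m.missing_fraction():.1f}%"
        )
    if run.diagnostics is not None:
        lines.append("composition homogeneity (chi-square):")
        for _, row in run.diagnostics.iterrows():
            lines.append(
                f"  {row['stratum']:>6}: chi2={row['chi2']:.1f} "
                f"df={int(row['df'])} p={row['p']:.3g} "
                f"mean GC={100 * row['mean_gc']:.1f}%"
            )
    if run.modelsel_table is not None:
        lines.append("partition-scheme comparison (AICc):")
        for _, row in run.modelsel_table.iterrows():
            lines.append(
                f"  {row['scheme']:>10}: partitions={row['n_partitions']:4d} "
                f"lnL={row['lnL']:.2f} AICc={row['AICc']:.2f} "
                f"dAICc={row['dAICc']:.2f}"
            )
    if run.decisiveness is not None:
        d = run.decisiveness
        lines.append(
            f"decisiveness: triplets {100 * d.fraction_triplets:.1f}% "
            f"quadruples {100 * d.fraction_quadruples:.1f}% ({d.mode})"
        )
    return "\n".join(lines)
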