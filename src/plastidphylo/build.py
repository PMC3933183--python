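"""Codon-aware supermatrix assembly.

Per-gene amino-acid alignments are trimmed by gap fraction, back-translated
to codon-aligned nucleotides against the source CDS (so the reading frame is
preserved exactly), and concatenated into a single supermatrix with per-gene
partition bookkeeping.  Missing taxon x gene blocks are filled with gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .types import (
    Alignment,
    GTR_G,
    Partition,
    PartitionScheme,
    PlastidPhyloError,
)

#: Default genetic code: NCBI translation table 11 (bacterial/plastid).
DEFAULT_CODE = 11

_STOP_CODONS: dict[int, frozenset] = {}
_CODON_MAP: dict[int, dict[str, str]] = {}


def _codon_table(code: int) -> tuple[dict[str, str], frozenset]:
    if code not in _CODON_MAP:
        table = CodonTable.unambiguous_dna_by_id[code]
        _CODON_MAP[code] = dict(table.forward_table)
        _STOP_CODONS[code] = frozenset(table.stop_codons)
    return _CODON_MAP[code], _STOP_CODONS[code]


def translate_cds(cds: str, code: int = DEFAULT_CODE) -> str:
    """Translate an ungapped CDS; terminal stop stripped, ambiguity -> 'X'.

    Raises on internal stop codons (with the 1-based codon position) and on
    lengths not divisible by three.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise PlastidPhyloError(
            f"CDS length {len(cds)} not divisible by 3"
        )
    fwd, stops = _codon_table(code)
    aa = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if codon in stops:
            if i == n_codons - 1:
                break  # terminal stop stripped
            raise PlastidPhyloError(
                f"internal stop codon {codon} at codon {i + 1}"
            )
        aa.append(fwd.get(codon, "X"))
    return "".join(aa)


def trim_columns(
    aa_aln: Alignment, max_gap_frac: float = 0.5
) -> tuple[Alignment, np.ndarray]:
    """Drop amino-acid columns whose gap fraction exceeds ``max_gap_frac``.

    Returns the trimmed alignment and the kept-column indices (0-based,
    relative to the untrimmed alignment).  This is a deliberately simple
    stand-in for heuristic alignment trimmers: a column survives iff
    gaps / n_taxa <= cutoff.
    """
    if not (0.0 <= max_gap_frac <= 1.0):
        raise PlastidPhyloError(f"max_gap_frac={max_gap_frac} outside [0,1]")
    arr = aa_aln.to_array()
    gap_frac = (arr == b"-").mean(axis=0)
    mask = np.flatnonzero(gap_frac <= max_gap_frac)
    if mask.size == 0:
        raise PlastidPhyloError("trimming removed every column (degenerate gene)")
    return aa_aln.subset_columns(mask), mask


def backtranslate(
    aa_aln: Alignment,
    cds_by_taxon: Mapping[str, str],
    trim_mask: Optional[np.ndarray] = None,
    code: int = DEFAULT_CODE,
) -> Alignment:
    """Expand an (untrimmed) AA alignment to a codon-aligned nt alignment.

    Each residue column becomes its source codon; AA gaps become ``---``;
    columns not in ``trim_mask`` are excluded (their codons are skipped but
    still consumed from the CDS).  Every taxon's CDS must translate exactly
    to its ungapped AA row.
    """
    keep = (
        np.asarray(trim_mask, dtype=np.intp)
        if trim_mask is not None
        else np.arange(aa_aln.n_columns)
    )
    keep_set = set(keep.tolist())
    nt_rows = []
    for taxon, row in zip(aa_aln.taxa, aa_aln.rows):
        cds = cds_by_taxon[taxon].upper().replace("U", "T")
        expected = translate_cds(cds, code=code)
        ungapped = row.replace("-", "")
        if ungapped != expected:
            diff = next(
                (i for i, (a, b) in enumerate(zip(ungapped, expected)) if a != b),
                min(len(ungapped), len(expected)),
            )
            raise PlastidPhyloError(
                f"CDS/AA mismatch for {taxon} at residue {diff + 1}: "
                f"alignment row translates to {ungapped[:diff + 1]!r}..., "
                f"CDS gives {expected[:diff + 1]!r}..."
            )
        out = []
        res_i = 0
        for col, ch in enumerate(row):
            if ch == "-":
                if col in keep_set:
                    out.append("---")
                continue
            if col in keep_set:
                out.append(cds[3 * res_i: 3 * res_i + 3])
            res_i += 1
        nt_rows.append("".join(out))
    phase = np.tile([1, 2, 3], len(keep))
    return Alignment(aa_aln.taxa, nt_rows, "nt", codon_phase=phase)


@dataclass
class GeneAlignment:
    """One gene's trimmed AA alignment with its codon-aligned nt counterpart."""

    gene_id: str
    aa_alignment: Alignment
    nt_alignment: Alignment
    trim_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.nt_alignment.n_columns != 3 * self.aa_alignment.n_columns:
            raise PlastidPhyloError(
                f"{self.gene_id}: nt columns != 3 x aa columns"
            )
        if self.aa_alignment.taxa != self.nt_alignment.taxa:
            raise PlastidPhyloError(f"{self.gene_id}: aa/nt taxon order differs")


def build_gene_alignment(
    gene_id: str,
    aa_aln: Alignment,
    cds_by_taxon: Mapping[str, str],
    max_gap_frac: float = 0.5,
    code: int = DEFAULT_CODE,
) -> GeneAlignment:
    """Trim an AA alignment and back-translate it in one step."""
    trimmed, mask = trim_columns(aa_aln, max_gap_frac)
    nt = backtranslate(aa_aln, cds_by_taxon, trim_mask=mask, code=code)
    return GeneAlignment(gene_id=gene_id, aa_alignment=trimmed,
                         nt_alignment=nt, trim_mask=mask)


def concatenate(
    genes: Sequence[GeneAlignment],
    taxa: Optional[Sequence[str]] = None,
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate per-gene nt alignments into a supermatrix.

    Genes are laid out in lexical order of ``gene_id``; absent taxon x gene
    blocks are filled with ``-``.  The returned scheme has one partition
    per gene (1-based inclusive ranges when written to file).
    """
    if not genes:
        raise PlastidPhyloError("nothing to concatenate")
    genes = sorted(genes, key=lambda g: g.gene_id)
    if taxa is None:
        seen: dict[str, None] = {}
        for g in genes:
            for t in g.nt_alignment.taxa:
                seen.setdefault(t)
        taxa = sorted(seen)
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    phases = []
    for g in genes:
        aln = g.nt_alignment
        if len(set(aln.taxa)) != len(aln.taxa):
            raise PlastidPhyloError(f"{g.gene_id}: duplicate taxon")
        L = aln.n_columns
        lookup = dict(zip(aln.taxa, aln.rows))
        blank = "-" * L
        for t in taxa:
            rows[t].append(lookup.get(t, blank))
        partitions.append(
            Partition(
                label=g.gene_id,
                columns=np.arange(offset, offset + L),
                model_family=GTR_G,
            )
        )
        phases.append(
            aln.codon_phase
            if aln.codon_phase is not None
            else np.tile([1, 2, 3], L // 3)
        )
        offset += L
    supermatrix = Alignment(
        list(taxa),
        ["".join(rows[t]) for t in taxa],
        "nt",
        codon_phase=np.concatenate(phases),
    )
    scheme = PartitionScheme(name="by_gene", partitions=partitions)
    return supermatrix, scheme


def remove_taxa(matrix: Alignment, taxa: Sequence[str]) -> Alignment:
    """Drop rows for ``taxa``; columns are left untouched (no re-trim)."""
    drop = set(taxa)
    unknown = drop - set(matrix.taxa)
    if unknown:
        raise PlastidPhyloError(f"unknown taxa: {sorted(unknown)}")
    keep = [t for t in matrix.taxa if t not in drop]
    if not keep:
        raise PlastidPhyloError("removing all taxa leaves an empty matrix")
    return matrix.subset_taxa(keep)
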