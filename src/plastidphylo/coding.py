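"""Character-coding variants of the codon supermatrix.

From the all-positions nucleotide matrix (ntAll) this module derives:

* ``ntNo3rd`` -- first and second codon positions only,
* ``nt3rdOnly`` -- third positions only,
* ``RY`` -- purine/pyrimidine binary recoding of ntAll,
* ``AA`` -- the translated amino-acid matrix,

remapping partition coordinates alongside.  RY-coding collapses A/G to R
and C/T to Y, which removes within-purine and within-pyrimidine
compositional differences among lineages (the usual motivation: GC content
can vary strongly across taxa while the RY composition stays homogeneous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .build import DEFAULT_CODE, _codon_table
from .types import (
    AA_G,
    Alignment,
    BIN_G,
    GTR_G,
    Partition,
    PartitionScheme,
    PlastidPhyloError,
)

CODING_NAMES = ("ntAll", "ntNo3rd", "nt3rdOnly", "RY", "AA")


@dataclass(frozen=True)
class CodingSpec:
    """One of the five character codings derived from the codon matrix."""

    name: str
    kept_phases: frozenset
    recode: str  # none | ry | translate

    def __post_init__(self) -> None:
        if self.name not in CODING_NAMES:
            raise PlastidPhyloError(f"unknown coding {self.name!r}")
        if self.recode == "translate" and self.kept_phases != frozenset({1, 2, 3}):
            raise PlastidPhyloError("AA coding requires all codon positions")
        if self.name == "RY" and self.recode != "ry":
            raise PlastidPhyloError("RY coding requires recode='ry'")


CODINGS = {
    "ntAll": CodingSpec("ntAll", frozenset({1, 2, 3}), "none"),
    "ntNo3rd": CodingSpec("ntNo3rd", frozenset({1, 2}), "none"),
    "nt3rdOnly": CodingSpec("nt3rdOnly", frozenset({3}), "none"),
    "RY": CodingSpec("RY", frozenset({1, 2, 3}), "ry"),
    "AA": CodingSpec("AA", frozenset({1, 2, 3}), "translate"),
}


def _remap_scheme(
    scheme: PartitionScheme,
    old_to_new: dict[int, int],
    name: str,
    model_family: Optional[str] = None,
) -> PartitionScheme:
    partitions = []
    for p in scheme.partitions:
        cols = [old_to_new[c] for c in p.columns.tolist() if c in old_to_new]
        if not cols:
            continue
        partitions.append(
            Partition(
                label=p.label,
                columns=np.asarray(sorted(set(cols))),
                model_family=model_family or p.model_family,
            )
        )
    return PartitionScheme(name=name, partitions=partitions)


def extract_positions(
    matrix: Alignment,
    phases: Sequence[int],
    scheme: Optional[PartitionScheme] = None,
) -> tuple[Alignment, Optional[PartitionScheme]]:
    """Keep columns whose codon phase is in ``phases``, remapping the scheme."""
    if matrix.codon_phase is None:
        raise PlastidPhyloError("matrix has no codon_phase metadata")
    phases = set(phases)
    if not phases or not phases <= {1, 2, 3}:
        raise PlastidPhyloError(f"invalid phase set {phases}")
    keep = np.flatnonzero(np.isin(matrix.codon_phase, sorted(phases)))
    sub = matrix.subset_columns(keep)
    new_scheme = None
    if scheme is not None:
        old_to_new = {int(c): i for i, c in enumerate(keep)}
        new_scheme = _remap_scheme(scheme, old_to_new, scheme.name)
    return sub, new_scheme


_RY_MAP = {}
for ch in "AGR":
    _RY_MAP[ch] = "R"
for ch in "CTY":
    _RY_MAP[ch] = "Y"
_RY_MAP["-"] = "-"
# all other IUPAC codes straddle the purine/pyrimidine divide -> unknown
for ch in "NWSKMBDHV?":
    _RY_MAP[ch] = "?"


def ry_recode(
    matrix: Alignment, scheme: Optional[PartitionScheme] = None
) -> tuple[Alignment, Optional[PartitionScheme]]:
    """Recode nucleotides as purine (R) / pyrimidine (Y) binary characters.

    A, G, R -> 'R'; C, T, Y -> 'Y'; gaps preserved; every other ambiguity
    code -> '?'.  Idempotent; column count unchanged.
    """
    if matrix.alphabet not in ("nt", "ry"):
        raise PlastidPhyloError("RY recoding needs a nucleotide matrix")
    table = str.maketrans(_RY_MAP)
    rows = [row.translate(table) for row in matrix.rows]
    out = Alignment(matrix.taxa, rows, "ry", codon_phase=matrix.codon_phase)
    new_scheme = None
    if scheme is not None:
        new_scheme = PartitionScheme(
            name=scheme.name,
            partitions=[
                Partition(p.label, p.columns, BIN_G) for p in scheme.partitions
            ],
        )
    return out, new_scheme


def translate_matrix(
    matrix: Alignment,
    scheme: Optional[PartitionScheme] = None,
    code: int = DEFAULT_CODE,
) -> tuple[Alignment, Optional[PartitionScheme]]:
    """Translate a codon supermatrix to amino acids, column count / 3.

    Per row: an all-gap codon becomes '-', a codon containing any ambiguity
    becomes 'X', a stop codon raises (it would mean a corrupted reading
    frame), and a half-gapped codon such as ``A--`` raises.
    """
    if matrix.codon_phase is None:
        raise PlastidPhyloError("matrix has no codon_phase metadata")
    phase = matrix.codon_phase
    L = matrix.n_columns
    if L % 3 != 0 or not np.array_equal(phase, np.tile([1, 2, 3], L // 3)):
        raise PlastidPhyloError("matrix is not complete in-frame codons")
    fwd, stops = _codon_table(code)
    aa_rows = []
    for taxon, row in zip(matrix.taxa, matrix.rows):
        out = []
        for i in range(0, L, 3):
            codon = row[i:i + 3]
            n_gap = codon.count("-")
            if n_gap == 3:
                out.append("-")
            elif n_gap > 0:
                raise PlastidPhyloError(
                    f"mixed gap codon {codon!r} for {taxon} at nt column {i + 1}"
                )
            elif codon in stops:
                raise PlastidPhyloError(
                    f"stop codon {codon} for {taxon} at nt column {i + 1}"
                )
            else:
                out.append(fwd.get(codon, "X"))
        aa_rows.append("".join(out))
    aa = Alignment(matrix.taxa, aa_rows, "aa")
    new_scheme = None
    if scheme is not None:
        old_to_new = {3 * j: j for j in range(L // 3)}
        new_scheme = _remap_scheme(scheme, old_to_new, scheme.name, AA_G)
    return aa, new_scheme


def derive_coding(
    matrix: Alignment,
    spec: CodingSpec | str,
    scheme: Optional[PartitionScheme] = None,
    code: int = DEFAULT_CODE,
) -> tuple[Alignment, Optional[PartitionScheme]]:
    """Apply one of the named codings to the codon supermatrix."""
    if isinstance(spec, str):
        spec = CODINGS[spec]
    out, out_scheme = matrix, scheme
    if spec.kept_phases != frozenset({1, 2, 3}):
        out, out_scheme = extract_positions(out, sorted(spec.kept_phases), out_scheme)
    if spec.recode == "ry":
        out, out_scheme = ry_recode(out, out_scheme)
    elif spec.recode == "translate":
        out, out_scheme = translate_matrix(out, out_scheme, code=code)
    if out_scheme is not None:
        out_scheme.name = f"{spec.name}_by_gene"
    return out, out_scheme


def codon_scheme(
    gene_scheme: PartitionScheme,
    codon_phase: np.ndarray,
    by_gene: bool = True,
    model_family: str = GTR_G,
) -> PartitionScheme:
    """Expand a by-gene scheme into codon-position partitions.

    ``by_gene=True`` gives one partition per (gene, position) -- e.g. 78
    genes -> 234 partitions; ``by_gene=False`` pools positions across genes
    (3 partitions).
    """
    phase = np.asarray(codon_phase)
    partitions = []
    if by_gene:
        for p in gene_scheme.partitions:
            for pos in (1, 2, 3):
                cols = p.columns[phase[p.columns] == pos]
                if len(cols):
                    partitions.append(
                        Partition(f"{p.label}_pos{pos}", cols, model_family)
                    )
        name = "by_codon_gene"
    else:
        for pos in (1, 2, 3):
            cols = np.flatnonzero(phase == pos)
            if len(cols):
                partitions.append(Partition(f"pos{pos}", cols, model_family))
        name = "by_codon"
    return PartitionScheme(name=name, partitions=partitions)


def single_partition_scheme(
    n_columns: int, model_family: str = GTR_G, name: str = "onepart"
) -> PartitionScheme:
    return PartitionScheme(
        name=name,
        partitions=[Partition("all", np.arange(n_columns), model_family)],
    )
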