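"""Shared domain types for the plastid phylogenomics pipeline.

Conventions used throughout the package:

* Column coordinates are **0-based half-open internally** and **1-based
  inclusive in all files** (matching RAxML-style partition files).
* Sequences are stored uppercased; ``U`` is mapped to ``T`` on input.
* Codon phase is recorded per column as 1, 2 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

NT_ALPHABET = "nt"
AA_ALPHABET = "aa"
RY_ALPHABET = "ry"

#: IUPAC nucleotide codes accepted in nt sequences (plus gap and missing).
IUPAC_NT = set("ACGTRYSWKMBDHVN-?")
#: Amino acid one-letter codes (plus ambiguity, gap and missing).
IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJ*-?")

#: Characters counted as "missing" in occupancy / missing-data statistics.
MISSING_CHARS = frozenset("-?NX")

GAP = "-"


class PlastidPhyloError(Exception):
    """Base class for all pipeline errors."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single taxon- (and optionally gene-) labelled sequence.

    ``gene_id`` may be empty before homolog clustering has assigned one; in
    that case it usually carries a per-taxon unique tag parsed from the FASTA
    header (convention ``taxon|tag``).
    """

    taxon_id: str
    gene_id: str
    seq: str
    alphabet: str = NT_ALPHABET

    def __post_init__(self) -> None:
        if not self.seq:
            raise PlastidPhyloError(f"empty sequence for taxon {self.taxon_id!r}")
        if any(ch.isspace() for ch in self.taxon_id) or not self.taxon_id:
            raise PlastidPhyloError(f"invalid taxon id {self.taxon_id!r}")
        if self.alphabet == NT_ALPHABET:
            bad = set(self.seq) - IUPAC_NT
            if bad:
                raise PlastidPhyloError(
                    f"non-IUPAC nucleotide characters {sorted(bad)} in "
                    f"{self.taxon_id}|{self.gene_id}"
                )

    @property
    def seq_id(self) -> str:
        """Unique sequence identifier ``taxon|gene``."""
        return f"{self.taxon_id}|{self.gene_id}" if self.gene_id else self.taxon_id


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity-search hit with derived coverages.

    ``query_cov``/``target_cov`` are the aligned-region length divided by the
    full query/target sequence length, in [0, 1].
    """

    query_id: str
    target_id: str
    evalue: float
    query_cov: float
    target_cov: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise PlastidPhyloError(f"negative e-value {self.evalue}")
        for name in ("query_cov", "target_cov"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PlastidPhyloError(f"{name}={v} outside [0, 1]")


class Alignment:
    """A rectangular character matrix over named taxa.

    Parameters
    ----------
    taxa:
        Ordered unique taxon labels.
    rows:
        One sequence per taxon, all the same length.
    alphabet:
        ``"nt"``, ``"aa"`` or ``"ry"``.
    codon_phase:
        Optional per-column phase array with values in {1, 2, 3}; required
        for codon-aware operations on nucleotide matrices.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence[str],
        alphabet: str,
        codon_phase: Optional[np.ndarray] = None,
    ) -> None:
        taxa = list(taxa)
        rows = [str(r).upper() for r in rows]
        if len(taxa) != len(rows):
            raise PlastidPhyloError("taxa/rows length mismatch")
        if len(set(taxa)) != len(taxa):
            raise PlastidPhyloError("duplicate taxon labels in alignment")
        if rows:
            L = len(rows[0])
            for t, r in zip(taxa, rows):
                if len(r) != L:
                    raise PlastidPhyloError(
                        f"row for {t} has length {len(r)}, expected {L}"
                    )
        if alphabet not in (NT_ALPHABET, AA_ALPHABET, RY_ALPHABET):
            raise PlastidPhyloError(f"unknown alphabet {alphabet!r}")
        if codon_phase is not None:
            codon_phase = np.asarray(codon_phase, dtype=np.int8)
            if rows and codon_phase.shape != (len(rows[0]),):
                raise PlastidPhyloError("codon_phase length != column count")
            if not np.isin(codon_phase, (1, 2, 3)).all():
                raise PlastidPhyloError("codon_phase values must be in {1,2,3}")
        self.taxa = taxa
        self.rows = rows
        self.alphabet = alphabet
        self.codon_phase = codon_phase

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise PlastidPhyloError(f"taxon {taxon!r} not in alignment") from None

    def to_array(self) -> np.ndarray:
        """Character matrix as a (n_taxa, n_columns) array of 1-byte strings."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_taxa, self.n_columns)

    def subset_columns(self, columns: np.ndarray) -> "Alignment":
        """New alignment keeping ``columns`` (0-based), in the given order."""
        columns = np.asarray(columns, dtype=np.intp)
        arr = self.to_array()[:, columns]
        rows = [row.tobytes().decode("ascii") for row in arr]
        phase = self.codon_phase[columns] if self.codon_phase is not None else None
        return Alignment(self.taxa, rows, self.alphabet, phase)

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise PlastidPhyloError(f"unknown taxa {missing}")
        rows = [self.rows[idx[t]] for t in taxa]
        return Alignment(list(taxa), rows, self.alphabet, self.codon_phase)

    def missing_fraction(self) -> float:
        """Fraction of cells that are gaps or ambiguous ('-', '?', 'N'/'X')."""
        if not self.rows or self.n_columns == 0:
            return 0.0
        arr = self.to_array()
        miss = np.zeros(arr.shape, dtype=bool)
        for ch in MISSING_CHARS:
            miss |= arr == ch.encode()
        return float(miss.mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        same_phase = (
            (self.codon_phase is None) == (other.codon_phase is None)
            and (
                self.codon_phase is None
                or np.array_equal(self.codon_phase, other.codon_phase)
            )
        )
        return (
            self.taxa == other.taxa
            and self.rows == other.rows
            and self.alphabet == other.alphabet
            and same_phase
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Alignment({self.n_taxa} taxa x {self.n_columns} cols, "
            f"{self.alphabet})"
        )


# Model families recognised by the likelihood engine.
GTR_G = "GTR+G"
BIN_G = "BIN+G"
AA_G = "AA+G"
MODEL_FAMILIES = (GTR_G, BIN_G, AA_G)


@dataclass(frozen=True)
class Partition:
    """A named set of alignment columns with an assigned model family."""

    label: str
    columns: np.ndarray  # 0-based column indices, sorted
    model_family: str = GTR_G

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=np.intp)
        object.__setattr__(self, "columns", np.sort(cols))
        if self.model_family not in MODEL_FAMILIES:
            raise PlastidPhyloError(f"unknown model family {self.model_family!r}")


@dataclass
class PartitionScheme:
    """Disjoint, exhaustive assignment of columns to model partitions.

    One set of branch lengths is shared by all partitions
    (``branch_linkage == "shared"``), matching how partitioned plastome
    analyses are normally run.
    """

    name: str
    partitions: list[Partition]
    branch_linkage: str = "shared"

    def __post_init__(self) -> None:
        if not self.partitions:
            raise PlastidPhyloError("a scheme needs at least one partition")
        all_cols = np.concatenate([p.columns for p in self.partitions])
        if len(np.unique(all_cols)) != len(all_cols):
            raise PlastidPhyloError(f"scheme {self.name!r}: partitions overlap")

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def n_columns(self) -> int:
        return sum(len(p.columns) for p in self.partitions)

    def validate_against(self, aln: Alignment) -> None:
        """Check that the scheme exactly covers the alignment's columns."""
        all_cols = np.sort(np.concatenate([p.columns for p in self.partitions]))
        if not np.array_equal(all_cols, np.arange(aln.n_columns)):
            raise PlastidPhyloError(
                f"scheme {self.name!r} does not cover alignment columns exactly"
            )


@dataclass
class CoverageMatrix:
    """Gene x taxon boolean presence matrix (the decisiveness substrate)."""

    genes: list[str]
    taxa: list[str]
    present: np.ndarray  # bool, shape (n_genes, n_taxa)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.genes), len(self.taxa)):
            raise PlastidPhyloError("coverage matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_gene_masks(self) -> list[int]:
        """Per-taxon bitmask of the genes present (bit g set iff gene g has
        the taxon)."""
        masks = []
        for j in range(self.n_taxa):
            m = 0
            for g in range(self.n_genes):
                if self.present[g, j]:
                    m |= 1 << g
            masks.append(m)
        return masks


@dataclass(frozen=True)
class LikelihoodResult:
    """The model-selection record for one partition scheme."""

    scheme_name: str
    n_partitions: int
    lnL: float
    k: int
    n: int
    AICc: float
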