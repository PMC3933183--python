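"""Readers and writers for the standard flat formats the pipeline touches.

Formats: FASTA, relaxed PHYLIP, Newick, 12-column BLAST tabular TSV, and
RAxML-style partition files (``DNA, name = a-b[\\3]``).  All file coordinates
are 1-based inclusive; in-memory coordinates are 0-based.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .types import (
    AA_ALPHABET,
    GTR_G,
    BIN_G,
    AA_G,
    Alignment,
    Partition,
    PartitionScheme,
    PlastidPhyloError,
    SequenceRecord,
    SimilarityHit,
)

HEADER_SEP = "|"


def _normalise(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "nt":
        seq = seq.replace("U", "T")
    return seq


def read_sequences(
    path: str,
    alphabet: str = "nt",
    sep: str = HEADER_SEP,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Headers are parsed as ``taxon[<sep>gene]``; anything after a second
    separator is ignored.  Sequences are uppercased and, for nucleotides,
    ``U`` is mapped to ``T``.  Duplicate ``(taxon, gene)`` pairs are an
    error.
    """
    # Pre-scan for malformed leading content so we can report a line number
    # (Bio.SeqIO silently skips leading junk).
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise PlastidPhyloError(
                    f"{path}:{lineno}: malformed FASTA (expected '>' header)"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for entry in SeqIO.parse(path, "fasta"):
        parts = entry.id.split(sep)
        taxon = parts[0]
        gene = parts[1] if len(parts) > 1 else ""
        if (taxon, gene) in seen:
            raise PlastidPhyloError(
                f"{path}: duplicate sequence id {taxon!r}|{gene!r}"
            )
        seen.add((taxon, gene))
        records.append(
            SequenceRecord(
                taxon_id=taxon,
                gene_id=gene,
                seq=_normalise(str(entry.seq), alphabet),
                alphabet=alphabet,
            )
        )
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.seq_id}\n{r.seq}\n")


def parse_hit_table(
    path: str,
    lengths: Mapping[str, int],
) -> list[SimilarityHit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    ``lengths`` maps sequence id to full (unaligned) length and is used to
    derive query/target coverages as ``(|end - start| + 1) / length``; the
    absolute value accommodates minus-orientation rows where end < start.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise PlastidPhyloError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, _pident, _alen, _mm, _gap,
             qstart, qend, sstart, send, evalue, bits) = fields
            try:
                ev = float(evalue)
                qs, qe, ss, se = int(qstart), int(qend), int(sstart), int(send)
                bit = float(bits)
            except ValueError as exc:
                raise PlastidPhyloError(f"{path}:{lineno}: {exc}") from None
            for name in (qid, sid):
                if name not in lengths:
                    raise PlastidPhyloError(
                        f"{path}:{lineno}: unknown sequence id {name!r} "
                        "when deriving coverage"
                    )
            qcov = (abs(qe - qs) + 1) / lengths[qid]
            tcov = (abs(se - ss) + 1) / lengths[sid]
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    target_id=sid,
                    evalue=ev,
                    query_cov=min(qcov, 1.0),
                    target_cov=min(tcov, 1.0),
                    bitscore=bit,
                )
            )
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], lengths: Mapping[str, int],
                    path: str) -> None:
    """Write hits back to 12-column BLAST tabular, reconstructing alignment
    coordinates from the stored coverages (1..round(cov*len))."""
    with open(path, "w") as fh:
        for h in hits:
            qlen = lengths[h.query_id]
            slen = lengths[h.target_id]
            qe = max(1, round(h.query_cov * qlen))
            se = max(1, round(h.target_cov * slen))
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.target_id, "100.00", str(qe), "0", "0",
                        "1", str(qe), "1", str(se),
                        f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Supermatrix (relaxed PHYLIP + partition file + FASTA)
# ---------------------------------------------------------------------------

_MODEL_TO_PREFIX = {GTR_G: "DNA", BIN_G: "BIN", AA_G: "WAG"}
_PREFIX_TO_MODEL = {"DNA": GTR_G, "BIN": BIN_G, "WAG": AA_G, "AA": AA_G}


def _columns_to_rangespec(columns: np.ndarray) -> str:
    """Render sorted 0-based columns as a 1-based RAxML range spec.

    Contiguous runs become ``a-b``; runs with constant stride 3 become
    ``a-b\\3`` (the codon-position dialect); anything else is a comma list
    of runs.
    """
    cols = np.asarray(columns) + 1  # 1-based
    if len(cols) == 0:
        raise PlastidPhyloError("empty partition")
    if len(cols) == 1:
        return f"{cols[0]}-{cols[0]}"
    diffs = np.diff(cols)
    if (diffs == 1).all():
        return f"{cols[0]}-{cols[-1]}"
    if (diffs == 3).all():
        return f"{cols[0]}-{cols[-1]}\\3"
    # general: comma-separated maximal runs (stride 1)
    parts = []
    start = prev = cols[0]
    for c in cols[1:]:
        if c == prev + 1:
            prev = c
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = c
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ", ".join(parts)


def write_partition_file(scheme: PartitionScheme, path: str) -> None:
    with open(path, "w") as fh:
        for p in scheme.partitions:
            prefix = _MODEL_TO_PREFIX[p.model_family]
            fh.write(f"{prefix}, {p.label} = {_columns_to_rangespec(p.columns)}\n")


_PART_LINE = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(.+?)\s*$")


def read_partition_file(path: str, name: Optional[str] = None) -> PartitionScheme:
    """Parse a RAxML-style partition file back into a scheme (0-based)."""
    partitions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _PART_LINE.match(line)
            if not m:
                raise PlastidPhyloError(f"{path}:{lineno}: bad partition line")
            prefix, label, spec = m.groups()
            model = _PREFIX_TO_MODEL.get(prefix.upper())
            if model is None:
                raise PlastidPhyloError(
                    f"{path}:{lineno}: unknown model prefix {prefix!r}"
                )
            cols: list[int] = []
            for chunk in spec.split(","):
                chunk = chunk.strip()
                stride = 1
                if "\\" in chunk:
                    chunk, stride_s = chunk.split("\\")
                    stride = int(stride_s)
                if "-" in chunk:
                    a, b = chunk.split("-")
                    cols.extend(range(int(a) - 1, int(b), stride))
                else:
                    cols.append(int(chunk) - 1)
            partitions.append(
                Partition(label=label, columns=np.asarray(cols), model_family=model)
            )
    return PartitionScheme(name=name or os.path.basename(path), partitions=partitions)


def write_phylip(aln: Alignment, path: str) -> None:
    """Relaxed PHYLIP: name and sequence separated by whitespace."""
    width = max(len(t) for t in aln.taxa) + 2
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.n_columns}\n")
        for t, row in zip(aln.taxa, aln.rows):
            fh.write(f"{t:<{width}}{row}\n")


def read_phylip(path: str, alphabet: str = "nt") -> Alignment:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise PlastidPhyloError(f"{path}: bad PHYLIP header")
        n_taxa, n_cols = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip())
    if len(taxa) != n_taxa or any(len(r) != n_cols for r in rows):
        raise PlastidPhyloError(f"{path}: PHYLIP dimensions disagree with header")
    return Alignment(taxa, rows, alphabet)


def write_fasta_alignment(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for t, row in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{row}\n")


def read_fasta_alignment(path: str, alphabet: str = "nt") -> Alignment:
    records = read_sequences(path, alphabet=alphabet, sep="\x00")  # keep ids whole
    return Alignment([r.taxon_id for r in records], [r.seq for r in records],
                     alphabet)


def write_supermatrix(
    aln: Alignment,
    scheme: PartitionScheme,
    out_dir: str,
    prefix: str = "supermatrix",
) -> dict[str, str]:
    """Write matrix as relaxed PHYLIP + FASTA + partition file.

    Returns a dict of logical name -> path.  The PHYLIP/partition pair
    round-trips losslessly through :func:`read_phylip` /
    :func:`read_partition_file`.
    """
    scheme.validate_against(aln)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "phylip": os.path.join(out_dir, f"{prefix}.phy"),
        "fasta": os.path.join(out_dir, f"{prefix}.fasta"),
        "partitions": os.path.join(out_dir, f"{prefix}.partitions.txt"),
    }
    write_phylip(aln, paths["phylip"])
    write_fasta_alignment(aln, paths["fasta"])
    write_partition_file(scheme, paths["partitions"])
    return paths


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree (unrooted by default)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise PlastidPhyloError(f"Newick parse error: {exc}") from exc
    return tree


def read_newick(path: str) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path: str) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(
        path=path, schema="newick", preserve_underscores=True
    )
    return list(trees)


def write_newick(tree: dendropy.Tree, path: Optional[str] = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Small tabular helpers (cluster tables, coverage matrices)
# ---------------------------------------------------------------------------

def write_cluster_table(clusters: Mapping[str, Sequence[str]],
                        taxon_of: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\ttaxon_id\tseq_id\n")
        for cid in sorted(clusters):
            for sid in sorted(clusters[cid]):
                fh.write(f"{cid}\t{taxon_of[sid]}\t{sid}\n")


def read_cluster_table(path: str) -> dict[str, list[str]]:
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            cid, _taxon, sid = line.rstrip("\n").split("\t")
            clusters.setdefault(cid, []).append(sid)
    return clusters


def write_coverage_tsv(cov, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(cov.taxa) + "\n")
        for g, row in zip(cov.genes, cov.present):
            fh.write(g + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")


def read_coverage_tsv(path: str):
    from .types import CoverageMatrix

    with open(path) as fh:
        taxa = fh.readline().rstrip("\n").split("\t")[1:]
        genes, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            rows.append([v == "1" for v in parts[1:]])
    return CoverageMatrix(genes=genes, taxa=taxa, present=np.asarray(rows))
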