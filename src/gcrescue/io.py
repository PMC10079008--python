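"""FASTA/FASTQ/Newick readers and writers.

FASTQ is fixed to 4-line records with Phred+33 qualities; other encodings are
rejected rather than guessed.  FASTA parsing is delegated to Biopython with
validation (unique ids, legal residues) layered on top.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .records import ReadRecord, SequenceRecord

logger = logging.getLogger(__name__)

FASTA_WRAP = 60
PHRED_OFFSET = 33


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Lowercase residues are uppercased.  ``*`` stop symbols are stripped from
    protein records with a warning.  Duplicate ids and illegal residues raise
    ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if "*" in residues:
            logger.warning("%s: stripping '*' stop symbols from record %r", path, rec.id)
            residues = residues.replace("*", "")
        description = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=residues, alphabet=alphabet,
                           description=description)
        )
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i:i + FASTA_WRAP] + "\n")


def read_fastq(path: str | Path, source_label: str = "") -> list[ReadRecord]:
    """Read 4-line FASTQ records with Phred+33 qualities (q = ord(char) - 33)."""
    path = Path(path)
    reads: list[ReadRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise ValueError(f"{path}: no records")
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated record at end of file")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: expected '@' header, got {head!r}")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: truncated record near line {i + 1}")
        read_id = head[1:].split()[0]
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: read {read_id!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        quals = [ord(c) - PHRED_OFFSET for c in qual]
        reads.append(ReadRecord(id=read_id, residues=seq, qualities=quals,
                                source_label=source_label))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as 4-line FASTQ; missing qualities default to Q30."""
    path = Path(path)
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities or [30] * len(read.residues)
            fh.write(f"@{read.id}\n{read.residues}\n+\n")
            fh.write("".join(chr(q + PHRED_OFFSET) for q in quals) + "\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`~gcrescue.phylo.PhyloTree` as Newick.

    Branch lengths are printed with 6 significant digits; bootstrap supports
    become internal-node labels; the string is terminated by ``;``.
    Unnamed leaves are an error.
    """
    text = tree.to_newick()
    with open(path, "w") as fh:
        fh.write(text + "\n")
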