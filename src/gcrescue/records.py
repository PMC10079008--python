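"""Core sequence containers shared by every pipeline stage.

Two alphabets are supported: DNA (A, C, G, T plus the ambiguity code N) and
protein (the 20 canonical amino acids plus X).  Residues are stored uppercase;
validation happens at construction so downstream code never re-checks.

Positions reported to users are 1-based inclusive; every internal interval is
0-based half-open.  Conversion happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA = "DNA"
PROTEIN = "PROTEIN"

DNA_ALPHABET = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def guess_alphabet(residues: str) -> str:
    """DNA when all residues are nucleotide codes, protein otherwise."""
    return DNA if set(residues) <= DNA_ALPHABET else PROTEIN


@dataclass
class SequenceRecord:
    """A named nucleotide or amino acid sequence.

    Parameters
    ----------
    id : str
        Short unique token identifying the record.
    residues : str
        Sequence letters; lowercase input is folded to uppercase.
    alphabet : str, optional
        ``"DNA"`` or ``"PROTEIN"``; inferred from the residues when omitted.
    description : str
        Free-text annotation carried through I/O.
    """

    id: str
    residues: str
    alphabet: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.alphabet is None:
            self.alphabet = guess_alphabet(self.residues)
        allowed = DNA_ALPHABET if self.alphabet == DNA else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != DNA:
            raise ValueError("reverse complement is defined for DNA only")
        return SequenceRecord(
            id=self.id,
            residues=revcomp(self.residues),
            alphabet=DNA,
            description=self.description,
        )


@dataclass
class ReadRecord:
    """A sequencing read: DNA residues, optional Phred qualities, source label.

    ``source_label`` names the tissue or dataset the read came from; the
    recruitment and expression stages group reads by it.
    """

    id: str
    residues: str
    qualities: list[int] | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read record requires a non-empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: illegal DNA residues {sorted(bad)}")
        if self.qualities is not None:
            if len(self.qualities) != len(self.residues):
                raise ValueError(
                    f"read {self.id!r}: quality length {len(self.qualities)} "
                    f"!= sequence length {len(self.residues)}"
                )
            if any(q < 0 or q > 60 for q in self.qualities):
                raise ValueError(f"read {self.id!r}: Phred quality outside [0, 60]")

    def __len__(self) -> int:
        return len(self.residues)
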