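"""Protein alignment: global pairwise (Needleman–Wunsch with affine gaps),
progressive multiple alignment over an NJ guide tree, and reference-numbered
position mapping.

Position mapping is what lets motif positions stated in a reference numbering
(e.g. human position 132) be transferred to every other sequence through the
alignment.

Gap convention matches the recruitment stage: a gap of length L costs
open + L * extend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .phylo import DistanceMatrix, TreeNode, nj_tree
from .records import SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _BLOSUM62.alphabet

GAP_OPEN = -10.0
GAP_EXTEND = -1.0

# 2D dict lookup is faster than the Array wrapper in the DP inner loop
BLOSUM62: dict[str, dict[str, float]] = {
    a: {b: float(_BLOSUM62[a][b]) for b in _B62_ALPHA} for a in _B62_ALPHA
}


@dataclass
class MSA:
    """Rows of equal length over residues + '-'; row order is meaningful."""

    ids: list[str]
    rows: list[str]
    validate: bool = True

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("MSA rows must all have the same length")
        if self.validate:
            n_cols = lengths.pop()
            for c in range(n_cols):
                if all(r[c] == "-" for r in self.rows):
                    raise ValueError(f"all-gap column at index {c}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in MSA") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


def nw_align(p1: str | SequenceRecord, p2: str | SequenceRecord,
             matrix: dict[str, dict[str, float]] | None = None,
             gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
             ) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps (Gotoh).

    Traceback ties prefer diagonal, then up (gap in the second sequence),
    then left.  Returns (aligned1, aligned2, score).
    """
    s1 = p1.residues if isinstance(p1, SequenceRecord) else p1
    s2 = p2.residues if isinstance(p2, SequenceRecord) else p2
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    sub = matrix or BLOSUM62
    m, n = len(s1), len(s2)
    NEG = -1e18
    go = gap_open + gap_extend
    ge = gap_extend

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in s2 (consumes s1): "up"
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in s1 (consumes s2): "left"
    for i in range(1, m + 1):
        X[i][0] = gap_open + i * ge
        H[i][0] = X[i][0]
    for j in range(1, n + 1):
        Y[0][j] = gap_open + j * ge
        H[0][j] = Y[0][j]
    for i in range(1, m + 1):
        row_s = sub[s1[i - 1]]
        Hi, Hi1, Xi, Xi1, Yi = H[i], H[i - 1], X[i], X[i - 1], Y[i]
        for j in range(1, n + 1):
            x = max(Hi1[j] + go, Xi1[j] + ge)
            y = max(Hi[j - 1] + go, Yi[j - 1] + ge)
            d = Hi1[j - 1] + row_s[s2[j - 1]]
            Xi[j] = x
            Yi[j] = y
            Hi[j] = d if d >= x and d >= y else (x if x >= y else y)

    a1: list[str] = []
    a2: list[str] = []
    i, j = m, n
    # state: which matrix the current cell's best value came from
    if H[i][j] == (H[i - 1][j - 1] + sub[s1[i - 1]][s2[j - 1]] if i and j else NEG):
        state = "M"
    elif H[i][j] == X[i][j]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            a1.append(s1[i - 1])
            a2.append(s2[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            d = H[i - 1][j - 1] + sub[s1[i - 1]][s2[j - 1]] if i and j else NEG
            if i and j and H[i][j] == d:
                state = "M"
            elif H[i][j] == X[i][j]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            a1.append(s1[i - 1])
            a2.append("-")
            opened = H[i - 1][j] + go
            i -= 1
            if X[i + 1][j] == opened:
                d = H[i - 1][j - 1] + sub[s1[i - 1]][s2[j - 1]] if i and j else NEG
                if i and j and H[i][j] == d:
                    state = "M"
                elif H[i][j] == X[i][j]:
                    state = "X"
                else:
                    state = "Y"
            # else stay in X (gap extension)
        else:
            a1.append("-")
            a2.append(s2[j - 1])
            opened = H[i][j - 1] + go
            j -= 1
            if Y[i][j + 1] == opened:
                d = H[i - 1][j - 1] + sub[s1[i - 1]][s2[j - 1]] if i and j else NEG
                if i and j and H[i][j] == d:
                    state = "M"
                elif H[i][j] == X[i][j]:
                    state = "X"
                else:
                    state = "Y"
    return "".join(reversed(a1)), "".join(reversed(a2)), H[m][n]


def alignment_identity(a1: str, a2: str) -> float:
    """Fraction of identical residue pairs over columns where both rows are
    residues; 0 when there is no such column."""
    both = [(x, y) for x, y in zip(a1, a2) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """L x (|alphabet|+1) column frequency matrix; last column is the gap."""
    alpha = _B62_ALPHA + "-"
    lookup = {c: k for k, c in enumerate(alpha)}
    L = len(rows[0])
    F = np.zeros((L, len(alpha)))
    for row in rows:
        for c, ch in enumerate(row):
            F[c, lookup[ch]] += 1
    return F / len(rows)


_SEXT = np.zeros((len(_B62_ALPHA) + 1, len(_B62_ALPHA) + 1))
for _i, _a in enumerate(_B62_ALPHA):
    for _j, _b in enumerate(_B62_ALPHA):
        _SEXT[_i, _j] = float(_BLOSUM62[_a][_b])
_SEXT[-1, :-1] = GAP_EXTEND   # residue vs existing gap
_SEXT[:-1, -1] = GAP_EXTEND
_SEXT[-1, -1] = 0.0


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with column-average scoring."""
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    S = FA @ _SEXT @ FB.T
    m, n = S.shape
    NEG = -1e18
    go = GAP_OPEN + GAP_EXTEND
    ge = GAP_EXTEND
    H = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = GAP_OPEN + i * ge
        H[i, 0] = X[i, 0]
    for j in range(1, n + 1):
        Y[0, j] = GAP_OPEN + j * ge
        H[0, j] = Y[0, j]
    for i in range(1, m + 1):
        Si = S[i - 1]
        for j in range(1, n + 1):
            x = max(H[i - 1, j] + go, X[i - 1, j] + ge)
            y = max(H[i, j - 1] + go, Y[i, j - 1] + ge)
            d = H[i - 1, j - 1] + Si[j - 1]
            X[i, j] = x
            Y[i, j] = y
            H[i, j] = d if d >= x and d >= y else (x if x >= y else y)
    # traceback on H with diagonal > up > left preference
    i, j = m, n
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == X[i, j]:
            cols_a.append(i - 1)
            cols_b.append(None)
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    new_a = ["".join(row[c] if c is not None else "-" for c in cols_a)
             for row in rows_a]
    new_b = ["".join(row[c] if c is not None else "-" for c in cols_b)
             for row in rows_b]
    return new_a, new_b


def progressive_msa(proteins: list[SequenceRecord]) -> MSA:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on pairwise (1 - identity) distances from
    global pairwise alignments.  Profiles are merged bottom-up in guide-tree
    order by profile–profile alignment with column-average BLOSUM62 scoring.
    Row order in the result matches the input order.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    if len(proteins) == 2:
        a1, a2, _ = nw_align(proteins[0], proteins[1])
        return MSA(ids=list(ids), rows=[a1, a2])

    n = len(proteins)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a1, a2, _ = nw_align(proteins[i], proteins[j])
            dmat[i, j] = dmat[j, i] = 1.0 - alignment_identity(a1, a2)
    guide = nj_tree(DistanceMatrix(labels=list(ids), matrix=dmat))

    by_id = {p.id: p for p in proteins}

    def build(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.name], [by_id[node.name].residues]
        parts = [build(ch) for ch in node.children]
        ids_acc, rows_acc = parts[0]
        for ids_b, rows_b in parts[1:]:
            rows_acc, rows_b = _profile_align(rows_acc, rows_b)
            ids_acc = ids_acc + ids_b
            rows_acc = rows_acc + rows_b
        return ids_acc, rows_acc

    got_ids, got_rows = build(guide.root)
    order = {gid: row for gid, row in zip(got_ids, got_rows)}
    return MSA(ids=list(ids), rows=[order[i] for i in ids])


def map_ref_position(msa: MSA, ref_id: str, ref_pos: int) -> dict[str, tuple[str, int | None]]:
    """Transfer a 1-based ungapped position in the reference row to all rows.

    Returns, per row id, the residue in the reference-anchored column ('-'
    allowed) and its 1-based ungapped position in that row (None for a gap).
    """
    ref_row = msa.row(ref_id)
    if not (1 <= ref_pos <= len(ref_row.replace("-", ""))):
        raise ValueError(f"ref_pos {ref_pos} outside ungapped length of {ref_id!r}")
    count = 0
    column = -1
    for c, ch in enumerate(ref_row):
        if ch != "-":
            count += 1
            if count == ref_pos:
                column = c
                break
    out: dict[str, tuple[str, int | None]] = {}
    for rid, row in zip(msa.ids, msa.rows):
        ch = row[column]
        if ch == "-":
            out[rid] = ("-", None)
        else:
            pos = sum(1 for x in row[:column + 1] if x != "-")
            out[rid] = (ch, pos)
    return out
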