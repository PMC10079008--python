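"""Homology-based read recruitment against a bait sequence.

Reads are recruited by exact k-mer seeding followed by banded local
(Smith–Waterman) extension with affine gaps, and kept when their bit score

    bits = (lambda * S - ln K) / ln 2

clears a threshold (100 bits by default, with match/mismatch = +1/-2 and
ungapped Karlin–Altschul constants lambda = 1.28, K = 0.46).  With these
defaults an exact match needs ~54 nt to reach 100 bits, which is the
effective length floor of recruitment.

Gap convention: a gap of length L costs open + L * extend (the first gapped
base pays both the open and the extend penalty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .records import ReadRecord, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

BAND_HALF_WIDTH = 15


@dataclass
class ScoringScheme:
    """Recruitment scoring parameters (BLASTN-like nucleotide scheme)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    k_const: float = 0.46
    bit_threshold: float = 100.0
    word_size: int = 11

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.k_const <= 0 or self.bit_threshold <= 0:
            raise ValueError("lambda, K and bit_threshold must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k_const)) / math.log(2)


@dataclass
class RecruitmentHit:
    """Best-scoring local alignment of one read against the bait.

    Intervals are 0-based half-open; ``bait_start/bait_end`` are always in
    forward bait coordinates.  ``strand`` is the read's strand relative to
    the bait.
    """

    read_id: str
    strand: str
    raw_score: int
    bit_score: float
    bait_start: int
    bait_end: int
    read_start: int
    read_end: int


class SeedIndex:
    """Exact-match lookup from every k-mer of the bait and of its reverse
    complement to (position, strand)."""

    def __init__(self, bait: str, k: int):
        if k > len(bait):
            raise ValueError("word size exceeds bait length")
        self.k = k
        self.bait = bait
        self.rc_bait = revcomp(bait)
        self.table: dict[str, list[tuple[int, str]]] = {}
        for strand, seq in (("+", bait), ("-", self.rc_bait)):
            for i in range(len(seq) - k + 1):
                self.table.setdefault(seq[i:i + k], []).append((i, strand))

    def n_kmers(self, strand: str) -> int:
        return sum(1 for hits in self.table.values()
                   for _, s in hits if s == strand)


def build_seed_index(bait: SequenceRecord | str, k: int = 11) -> SeedIndex:
    seq = bait.residues if isinstance(bait, SequenceRecord) else bait
    return SeedIndex(seq, k)


def _banded_sw(query: str, target: str, diagonal: int, scheme: ScoringScheme,
               band: int = BAND_HALF_WIDTH):
    """Banded local alignment around ``diagonal`` (= target_pos - query_pos).

    Returns (raw_score, query interval, target interval), 0-based half-open,
    or None when the best score is 0.
    """
    m, n = len(query), len(target)
    width = 2 * band + 1
    NEG = -(10 ** 9)
    match, mis = scheme.match, scheme.mismatch
    go = scheme.gap_open + scheme.gap_extend   # first gapped base
    ge = scheme.gap_extend

    # cell (i, j), 1-based, lives at band offset o = j - (i + diagonal) + band;
    # cells (i-1, j-1) and (i-1, j) of the previous row live at offsets o and
    # o+1 respectively.  Each cell carries the origin (start cell) of the best
    # local alignment ending there, so no traceback matrices are needed.
    prev_h = [0] * width
    prev_f = [NEG] * width
    prev_horg: list = [None] * width
    prev_forg: list = [None] * width
    best = (0, 0, 0)
    best_org = None
    for i in range(1, m + 1):
        cur_h = [0] * width
        cur_f = [NEG] * width
        cur_horg: list = [None] * width
        cur_forg: list = [None] * width
        qc = query[i - 1]
        e = NEG
        e_org = None
        lo = max(1, i + diagonal - band)
        hi = min(n, i + diagonal + band)
        for j in range(lo, hi + 1):
            o = j - (i + diagonal) + band
            if j == 1:
                diag_h, diag_org = 0, None
            else:
                diag_h, diag_org = prev_h[o], prev_horg[o]
            sub = diag_h + (match if qc == target[j - 1] else mis)
            sub_org = diag_org if diag_org is not None else (i - 1, j - 1)
            # E: gap consuming target, extends along the row
            if o >= 1:
                open_e = cur_h[o - 1] + go
                ext_e = e + ge
                if open_e >= ext_e:
                    e, e_org = open_e, cur_horg[o - 1]
                else:
                    e = ext_e
            else:
                e, e_org = NEG, None
            # F: gap consuming query, extends down the column
            if o + 1 < width:
                open_f = prev_h[o + 1] + go
                ext_f = prev_f[o + 1] + ge
                if open_f >= ext_f:
                    f, f_org = open_f, prev_horg[o + 1]
                else:
                    f, f_org = ext_f, prev_forg[o + 1]
            else:
                f, f_org = NEG, None
            cur_f[o], cur_forg[o] = f, f_org
            h, org = sub, sub_org
            if e > h:
                h, org = e, e_org
            if f > h:
                h, org = f, f_org
            if h <= 0:
                h, org = 0, None
            cur_h[o] = h
            cur_horg[o] = org
            if h > best[0]:
                best = (h, i, j)
                best_org = org
        prev_h, prev_f = cur_h, cur_f
        prev_horg, prev_forg = cur_horg, cur_forg
    if best[0] <= 0:
        return None
    score, ei, ej = best
    si, sj = best_org if best_org is not None else (ei - 1, ej - 1)
    return score, (si, ei), (sj, ej)


def score_read(read: ReadRecord | str, bait: SequenceRecord | str,
               index: SeedIndex, scheme: ScoringScheme | None = None,
               ) -> RecruitmentHit | None:
    """Best banded local alignment of a read against the bait over all seeds
    and strands; None when no k-mer seed matches."""
    scheme = scheme or ScoringScheme()
    seq = read.residues if isinstance(read, ReadRecord) else read
    read_id = read.id if isinstance(read, ReadRecord) else ""
    k = index.k
    if len(seq) < k:
        return None
    diagonals: set[tuple[str, int]] = set()
    table = index.table
    for r in range(len(seq) - k + 1):
        hits = table.get(seq[r:r + k])
        if hits:
            for pos, strand in hits:
                diagonals.add((strand, pos - r))
    if not diagonals:
        return None
    n = len(index.bait)
    best: RecruitmentHit | None = None
    for strand, diag in sorted(diagonals):
        target = index.bait if strand == "+" else index.rc_bait
        res = _banded_sw(seq, target, diag, scheme)
        if res is None:
            continue
        raw, (qs, qe), (ts, te) = res
        if strand == "-":
            ts, te = n - te, n - ts
        hit = RecruitmentHit(
            read_id=read_id, strand=strand, raw_score=raw,
            bit_score=scheme.bit_score(raw),
            bait_start=ts, bait_end=te, read_start=qs, read_end=qe,
        )
        if (best is None
                or hit.raw_score > best.raw_score
                or (hit.raw_score == best.raw_score and hit.bait_start < best.bait_start)
                or (hit.raw_score == best.raw_score and hit.bait_start == best.bait_start
                    and hit.strand == "+" and best.strand == "-")):
            best = hit
    return best


def recruit(reads: list[ReadRecord], bait: SequenceRecord,
            scheme: ScoringScheme | None = None) -> list[RecruitmentHit]:
    """Recruit reads whose best hit clears the bit-score threshold.

    One best hit per read; output preserves input read order.
    """
    scheme = scheme or ScoringScheme()
    index = build_seed_index(bait, scheme.word_size)
    hits: list[RecruitmentHit] = []
    for read in reads:
        hit = score_read(read, bait, index, scheme)
        if hit is not None and hit.bit_score >= scheme.bit_threshold:
            hits.append(hit)
    logger.info(
        "recruit: %d/%d reads recruited against bait %r at %.0f-bit threshold",
        len(hits), len(reads), bait.id, scheme.bit_threshold,
    )
    return hits
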