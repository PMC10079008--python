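"""Greedy overlap-layout-consensus assembly of recruited reads.

The assembler repeatedly merges the contig/read pair with the longest
suffix–prefix overlap (>= ``min_overlap``, mismatch rate <=
``max_mismatch_rate``), considering both orientations, until no merge
qualifies.  Consensus per column is a weighted majority vote (weights = base
qualities when present, else 1) with ties broken by the fixed base order
A < C < G < T.

Candidate overlaps are seeded with shared exact 12-mers, so a qualifying
overlap is found whenever it contains one clean 12-mer — essentially always
at the substitution rates this pipeline targets (<= ~2%).

`iterative_rescue` wraps recruit -> assemble rounds, promoting the longest
contig to be the next round's bait, which is how a short or diverged initial
bait grows into a full-length coding sequence.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .records import DNA, ReadRecord, SequenceRecord, revcomp
from .recruit import ScoringScheme, build_seed_index, recruit, score_read
from .synthetic import translate

logger = logging.getLogger(__name__)

OVERLAP_KMER = 12
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Contig:
    """Assembled consensus with per-base depth and the read layout."""

    consensus: str
    depth: list[int]
    layout: list[tuple[str, int, str, int]]   # (read_id, offset, orientation, length)

    @property
    def n_reads(self) -> int:
        return len(self.layout)

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Orf:
    """Open reading frame ATG..stop; interval in forward contig coordinates,
    0-based half-open, stop codon included."""

    start: int
    end: int
    strand: str
    frame: int
    translation: str
    is_candidate: bool = False


class _Frag:
    """Working contig: per-column weight counts plus derived consensus."""

    __slots__ = ("counts", "depth", "layout", "name", "consensus", "arr",
                 "kmers", "kset", "rc_kset")

    def __init__(self, counts: np.ndarray, depth: np.ndarray,
                 layout: list[tuple[str, int, str, int]], name: str):
        self.counts = counts
        self.depth = depth
        self.layout = layout
        self.name = name
        self._refresh()

    @classmethod
    def from_read(cls, read: ReadRecord) -> "_Frag":
        L = len(read.residues)
        counts = np.zeros((L, 4), dtype=np.float64)
        weights = read.qualities if read.qualities is not None else [1] * L
        for i, (b, w) in enumerate(zip(read.residues, weights)):
            idx = _BASE_INDEX.get(b)
            if idx is not None:
                counts[i, idx] = max(w, 1)
        depth = np.ones(L, dtype=np.int64)
        return cls(counts, depth, [(read.id, 0, "+", L)], read.id)

    def _refresh(self) -> None:
        cons_idx = self.counts.argmax(axis=1)   # argmax tie -> lowest index = A<C<G<T
        self.arr = _BASES[cons_idx]
        covered = self.counts.sum(axis=1) > 0
        arr = self.arr.copy()
        arr[~covered] = ord("N")
        self.arr = arr
        self.consensus = arr.tobytes().decode()
        k = OVERLAP_KMER
        kmers: dict[str, list[int]] = {}
        s = self.consensus
        for i in range(len(s) - k + 1):
            kmers.setdefault(s[i:i + k], []).append(i)
        self.kmers = kmers
        self.kset = frozenset(kmers)
        self.rc_kset = frozenset(revcomp(w) for w in self.kset)

    def __len__(self) -> int:
        return len(self.consensus)

    def flipped(self) -> "_Frag":
        L = len(self)
        counts = self.counts[::-1, ::-1].copy()   # reverse positions, A<->T C<->G
        depth = self.depth[::-1].copy()
        layout = [(rid, L - off - ln, "-" if ori == "+" else "+", ln)
                  for rid, off, ori, ln in self.layout]
        return _Frag(counts, depth, layout, self.name)


def _best_shift(x: _Frag, y: _Frag, min_overlap: int,
                max_mismatch_rate: float) -> tuple[int, int] | None:
    """Longest qualifying placement of y starting inside x (shift >= 0).

    Returns (overlap_length, shift) or None.  Candidate shifts come from
    shared exact k-mers.
    """
    shifts: set[int] = set()
    xk, yk = x.kmers, y.kmers
    smaller, other, flip = (yk, xk, True) if len(yk) <= len(xk) else (xk, yk, False)
    for w, positions in smaller.items():
        opos = other.get(w)
        if not opos:
            continue
        for q in positions:
            for p in opos:
                s = (p - q) if flip else (q - p)
                if s >= 0:
                    shifts.add(s)
    best: tuple[int, int] | None = None
    lx, ly = len(x), len(y)
    for s in sorted(shifts):
        ov = min(lx - s, ly)
        if ov < min_overlap:
            continue
        if best is not None and best[0] >= ov:
            continue
        mism = int((x.arr[s:s + ov] != y.arr[:ov]).sum())
        if mism <= max_mismatch_rate * ov:
            best = (ov, s)
    return best


def _best_merge(x: _Frag, y: _Frag, min_overlap: int, max_mismatch_rate: float):
    """Best qualifying merge over the four orientation layouts.

    Returns (overlap, result_len, combo, shift) or None, where combo is one of
    'xy', 'yx', 'xY', 'Yx' (capital = y reverse-complemented).
    """
    candidates = []
    same = bool(x.kset & y.kset)
    oppo = bool(x.kset & y.rc_kset)
    y_rc = y.flipped() if oppo else None
    if same:
        for combo, (a, b) in (("xy", (x, y)), ("yx", (y, x))):
            r = _best_shift(a, b, min_overlap, max_mismatch_rate)
            if r:
                ov, s = r
                candidates.append((ov, max(len(a), s + len(b)), combo, s))
    if oppo:
        for combo, (a, b) in (("xY", (x, y_rc)), ("Yx", (y_rc, x))):
            r = _best_shift(a, b, min_overlap, max_mismatch_rate)
            if r:
                ov, s = r
                candidates.append((ov, max(len(a), s + len(b)), combo, s))
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[0], c[1], c[2]))


def _merge(x: _Frag, y: _Frag, combo: str, shift: int) -> _Frag:
    if combo == "yx":
        x, y = y, x
    elif combo == "xY":
        y = y.flipped()
    elif combo == "Yx":
        x, y = y.flipped(), x
    new_len = max(len(x), shift + len(y))
    counts = np.zeros((new_len, 4), dtype=np.float64)
    depth = np.zeros(new_len, dtype=np.int64)
    counts[:len(x)] += x.counts
    depth[:len(x)] += x.depth
    counts[shift:shift + len(y)] += y.counts
    depth[shift:shift + len(y)] += y.depth
    layout = list(x.layout) + [(rid, off + shift, ori, ln)
                               for rid, off, ori, ln in y.layout]
    return _Frag(counts, depth, layout, min(x.name, y.name))


def greedy_assemble(reads: list[ReadRecord], min_overlap: int = 30,
                    max_mismatch_rate: float = 0.02) -> list[Contig]:
    """Assemble reads into contigs by greedy longest-overlap-first merging.

    Ties on overlap length are broken by longer resulting contig, then by
    lexicographic contig ids.  Contigs are returned sorted by length
    descending.
    """
    if not reads:
        raise ValueError("at least one read required")
    live: dict[int, _Frag] = {}
    token = itertools.count()
    for read in reads:
        live[next(token)] = _Frag.from_read(read)

    heap: list = []

    def push_pairs(ta: int, tokens) -> None:
        a = live[ta]
        for tb in tokens:
            if tb == ta:
                continue
            b = live[tb]
            m = _best_merge(a, b, min_overlap, max_mismatch_rate)
            if m:
                ov, rlen, combo, shift = m
                key = tuple(sorted((a.name, b.name)))
                heapq.heappush(heap, (-ov, -rlen, key, ta, tb, combo, shift))

    tokens0 = list(live)
    for i, ta in enumerate(tokens0):
        push_pairs(ta, tokens0[i + 1:])

    while heap:
        neg_ov, neg_rlen, _key, ta, tb, combo, shift = heapq.heappop(heap)
        if ta not in live or tb not in live:
            continue
        merged = _merge(live.pop(ta), live.pop(tb), combo, shift)
        tm = next(token)
        live[tm] = merged
        push_pairs(tm, [t for t in live if t != tm])

    contigs = [Contig(consensus=f.consensus, depth=[int(d) for d in f.depth],
                      layout=list(f.layout))
               for f in live.values()]
    contigs.sort(key=lambda c: (-len(c), c.layout[0][0]))
    logger.info("greedy_assemble: %d reads -> %d contigs (longest %d nt)",
                len(reads), len(contigs), len(contigs[0]))
    return contigs


def orient_to_bait(contig: Contig, bait: SequenceRecord,
                   scheme: ScoringScheme | None = None) -> Contig:
    """Canonical orientation: the strand whose alignment to the bait scores
    higher.  Leaves the contig unchanged when it does not align at all."""
    scheme = scheme or ScoringScheme()
    index = build_seed_index(bait, scheme.word_size)
    hit = score_read(contig.consensus, bait, index, scheme)
    if hit is not None and hit.strand == "-":
        L = len(contig.consensus)
        return Contig(
            consensus=revcomp(contig.consensus),
            depth=contig.depth[::-1],
            layout=[(rid, L - off - ln, "-" if ori == "+" else "+", ln)
                    for rid, off, ori, ln in contig.layout],
        )
    return contig


def iterative_rescue(reads: list[ReadRecord], initial_bait: SequenceRecord,
                     scheme: ScoringScheme | None = None, max_rounds: int = 5,
                     min_overlap: int = 30, max_mismatch_rate: float = 0.02,
                     ) -> tuple[Contig, list[int]]:
    """Iterate recruit -> assemble, promoting the longest contig to next bait.

    Stops when the recruited-read set is unchanged between rounds or after
    ``max_rounds``.  Returns the final longest contig (oriented to the
    original bait) and the per-round recruitment counts.
    """
    scheme = scheme or ScoringScheme()
    by_id = {r.id: r for r in reads}
    bait = initial_bait
    prev_ids: set[str] | None = None
    counts: list[int] = []
    contig: Contig | None = None
    for round_no in range(1, max_rounds + 1):
        hits = recruit(reads, bait, scheme)
        ids = {h.read_id for h in hits}
        counts.append(len(ids))
        logger.info("rescue round %d: %d reads recruited", round_no, len(ids))
        if round_no == 1 and not ids:
            raise ValueError("no reads recruited in round 1: "
                             "bait too diverged or threshold too strict")
        if prev_ids is not None and ids == prev_ids:
            break
        recruited = [by_id[h.read_id] for h in hits]
        contigs = greedy_assemble(recruited, min_overlap, max_mismatch_rate)
        contig = orient_to_bait(contigs[0], initial_bait, scheme)
        bait = SequenceRecord(id=f"{initial_bait.id}_round{round_no}",
                              residues=contig.consensus, alphabet=DNA)
        prev_ids = ids
    assert contig is not None
    return contig, counts


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(contig: Contig | SequenceRecord | str, min_aa: int = 50) -> list[Orf]:
    """ATG..stop open reading frames in all 6 frames, length >= min_aa codons.

    Intervals are reported in forward contig coordinates (0-based half-open,
    stop codon included); the longest ORF is flagged as the candidate CDS.
    """
    if isinstance(contig, Contig):
        seq = contig.consensus
    elif isinstance(contig, SequenceRecord):
        seq = contig.residues
    else:
        seq = contig.upper()
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start = None
            for i in range(frame, L - 2, 3):
                codon = s[i:i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOPS:
                    aa = (i - start) // 3
                    if aa >= min_aa:
                        b, e = start, i + 3
                        if strand == "-":
                            b, e = L - e, L - b
                        orfs.append(Orf(start=b, end=e, strand=strand, frame=frame,
                                        translation=translate(s[start:i])))
                    start = None
    orfs.sort(key=lambda o: (o.start, o.strand))
    if orfs:
        best = max(orfs, key=lambda o: (len(o.translation), -o.start,
                                        o.strand == "+"))
        best.is_candidate = True
    return orfs
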