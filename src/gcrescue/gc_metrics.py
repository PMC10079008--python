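"""GC-content and G/C-stretch statistics for coding sequences.

A G/C stretch is a maximal run of consecutive G or C nucleotides of at least
a minimum length (3 by default).  Long stretches impede both sequencing and
assembly, which is how extremely GC-rich genes end up missing from genome
assemblies; the per-gene mean stretch length is the statistic that separates
such genes from a normal-GC background.

N handling is conservative: N terminates a run and is excluded from the GC
fraction, so ambiguity codes can never inflate either statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .records import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_STRETCH = 3
DEFAULT_MIN_CDS_LENGTH = 300
HISTOGRAM_BIN_WIDTH = 0.1


@dataclass
class StretchProfile:
    """Per-CDS GC fraction plus G/C-run intervals and summary statistics."""

    sequence_id: str
    length_nt: int
    gc_fraction: float
    stretches: list[tuple[int, int]]
    min_stretch_length: int = DEFAULT_MIN_STRETCH

    @property
    def stretch_count(self) -> int:
        return len(self.stretches)

    @property
    def mean_stretch_length(self) -> float:
        if not self.stretches:
            return 0.0
        return sum(e - s for s, e in self.stretches) / len(self.stretches)


@dataclass
class GeneSetProfile:
    """Background profile of a CDS set: per-gene table plus a histogram of
    mean stretch lengths (bin width 0.1)."""

    profiles: list[StretchProfile]
    n_filtered: int
    min_cds_length: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def percentile_rank(self, query: StretchProfile) -> float:
        """Percent of background genes with mean stretch length <= the query's."""
        values = [p.mean_stretch_length for p in self.profiles]
        below = sum(1 for v in values if v <= query.mean_stretch_length)
        return 100.0 * below / len(values)


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both sides."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC fraction undefined: sequence has no A/C/G/T bases")
    return gc / acgt


def gc_stretches(seq: str, min_len: int = DEFAULT_MIN_STRETCH) -> list[tuple[int, int]]:
    """Maximal runs of G/C with length >= min_len, as sorted 0-based
    half-open intervals.  N (or any non-G/C base) breaks a run."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    out: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch in "GC":
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                out.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_len:
        out.append((start, len(seq)))
    return out


def stretch_summary(record: SequenceRecord, min_len: int = DEFAULT_MIN_STRETCH) -> StretchProfile:
    """GC fraction and stretch statistics for one CDS."""
    return StretchProfile(
        sequence_id=record.id,
        length_nt=len(record.residues),
        gc_fraction=gc_fraction(record.residues),
        stretches=gc_stretches(record.residues, min_len),
        min_stretch_length=min_len,
    )


def gene_set_profile(
    cds_set: list[SequenceRecord],
    min_len: int = DEFAULT_MIN_STRETCH,
    min_cds_length: int = DEFAULT_MIN_CDS_LENGTH,
) -> GeneSetProfile:
    """Profile a CDS background: filter short sequences, profile the rest,
    and histogram the per-gene mean stretch lengths.

    Sequences shorter than ``min_cds_length`` are dropped (count logged).
    """
    kept = [r for r in cds_set if len(r.residues) >= min_cds_length]
    n_filtered = len(cds_set) - len(kept)
    logger.info(
        "gene_set_profile: %d input CDS, %d filtered (< %d nt), %d profiled",
        len(cds_set), n_filtered, min_cds_length, len(kept),
    )
    if not kept:
        raise ValueError(f"no CDS of length >= {min_cds_length} nt to profile")
    profiles = [stretch_summary(r, min_len) for r in kept]
    means = np.array([p.mean_stretch_length for p in profiles])
    top = math.floor(means.max() / HISTOGRAM_BIN_WIDTH) + 1
    edges = np.arange(0, (top + 1)) * HISTOGRAM_BIN_WIDTH
    counts, _ = np.histogram(means, bins=edges)
    return GeneSetProfile(
        profiles=profiles,
        n_filtered=n_filtered,
        min_cds_length=min_cds_length,
        bin_edges=edges,
        bin_counts=counts,
    )
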