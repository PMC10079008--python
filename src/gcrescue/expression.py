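"""Tissue expression profiling by read recruitment and RPKM normalization.

Per tissue, reads recruited against the gene of interest are counted and
normalized as RPKM = count / ((gene_length/1000) x (library_size/10^6)).
The library size is the total number of reads in the dataset (not "mapped"
reads: recruitment operates on whole read sets where no genome-wide mapping
exists, so total-read normalization is the only computable denominator).

Immune enrichment is an artifact-defined score: the immune/non-immune median
RPKM ratio, plus a flag that is true exactly when every immune tissue's RPKM
exceeds the median RPKM of the non-immune tissues.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .records import ReadRecord, SequenceRecord
from .recruit import ScoringScheme, recruit

logger = logging.getLogger(__name__)


@dataclass
class ExpressionRecord:
    tissue: str
    count: int
    library_size: int
    gene_length_nt: int
    rpkm: float
    immune: bool


@dataclass
class EnrichmentReport:
    """Records sorted by RPKM descending, median-based enrichment summary."""

    records: list[ExpressionRecord]
    immune_median: float
    nonimmune_median: float
    ratio: float | None        # None when a median is zero
    enriched: bool


def rpkm(count: int, gene_length_nt: int, library_size: int) -> float:
    """Reads per kilobase of gene per million library reads."""
    if gene_length_nt < 1:
        raise ValueError("gene length must be >= 1")
    if library_size < 1:
        raise ValueError("library size must be >= 1")
    return count / ((gene_length_nt / 1000.0) * (library_size / 1e6))


def count_recruited(tissue_read_sets: dict[str, list[ReadRecord]],
                    bait: SequenceRecord,
                    scheme: ScoringScheme | None = None,
                    ) -> dict[str, tuple[int, int]]:
    """Per-tissue (recruited count, library size); tissues are independent.

    An empty read set yields count 0 with a warning rather than an error.
    """
    scheme = scheme or ScoringScheme()
    out: dict[str, tuple[int, int]] = {}
    for tissue, reads in tissue_read_sets.items():
        if not reads:
            logger.warning("tissue %r: empty read set, count 0", tissue)
            out[tissue] = (0, 0)
            continue
        hits = recruit(reads, bait, scheme)
        out[tissue] = (len(hits), len(reads))
        logger.info("tissue %r: %d/%d reads recruited", tissue, len(hits), len(reads))
    return out


def enrichment_report(records: list[ExpressionRecord],
                      immune_flags: dict[str, bool] | None = None,
                      ) -> EnrichmentReport:
    """Summarize immune vs non-immune expression.

    ``immune_flags`` overrides the per-record flags when given; a tissue
    missing from the map is an error.
    """
    if immune_flags is not None:
        missing = [r.tissue for r in records if r.tissue not in immune_flags]
        if missing:
            raise ValueError(f"immune flag missing for tissues: {missing}")
        records = [ExpressionRecord(r.tissue, r.count, r.library_size,
                                    r.gene_length_nt, r.rpkm,
                                    immune_flags[r.tissue])
                   for r in records]
    immune = [r.rpkm for r in records if r.immune]
    non = [r.rpkm for r in records if not r.immune]
    if not immune or not non:
        raise ValueError("need at least one immune and one non-immune tissue")
    med_i = statistics.median(immune)
    med_n = statistics.median(non)
    ratio = (med_i / med_n) if (med_i > 0 and med_n > 0) else None
    enriched = all(v > med_n for v in immune)
    ordered = sorted(records, key=lambda r: (-r.rpkm, r.tissue))
    return EnrichmentReport(records=ordered, immune_median=med_i,
                            nonimmune_median=med_n, ratio=ratio,
                            enriched=enriched)


def quantify(tissue_read_sets: dict[str, list[ReadRecord]],
             bait: SequenceRecord, immune_flags: dict[str, bool],
             scheme: ScoringScheme | None = None) -> EnrichmentReport:
    """Recruit, count, normalize and summarize in one call."""
    counts = count_recruited(tissue_read_sets, bait, scheme)
    gene_len = len(bait.residues)
    records = []
    for tissue, (count, lib) in counts.items():
        if tissue not in immune_flags:
            raise ValueError(f"immune flag missing for tissue {tissue!r}")
        value = rpkm(count, gene_len, lib) if lib > 0 else 0.0
        records.append(ExpressionRecord(
            tissue=tissue, count=count, library_size=lib,
            gene_length_nt=gene_len, rpkm=value, immune=immune_flags[tissue],
        ))
    return enrichment_report(records)
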