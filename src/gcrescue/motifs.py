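"""Signaling-motif scanning on adaptor-family proteins.

The scanned panel reflects what makes a LAT-family sequence functionally
credible: the juxtamembrane palmitoylation cysteine pair (C-x(1,4)-C near the
N terminus), the PLCγ-recruiting tyrosine with its N-terminal context residue
(glycine in tetrapods makes it a suboptimal ZAP-70 substrate; aspartate or
glutamate in some fish makes it optimal), Grb2-type Y-x-N docking sites, the
LCK-binding hexapeptide PIPRSP, and overall proline richness of the
membrane-proximal intracellular region.

All reported positions are 1-based on the ungapped query sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .align import MSA, map_ref_position
from .records import SequenceRecord


@dataclass
class MotifConfig:
    """Patterns and windows for the motif panel (regular expressions)."""

    dicysteine_pattern: str = r"C.{1,4}C"
    dicysteine_window: tuple[int, int] = (1, 45)
    plc_pattern: str = "YLVV"
    grb2_pattern: str = "Y.N"
    lck_motif: str = "PIPRSP"
    proline_region: tuple[int, int] = (30, 100)

    def __post_init__(self) -> None:
        for pat in (self.dicysteine_pattern, self.plc_pattern,
                    self.grb2_pattern, self.lck_motif):
            if not pat:
                raise ValueError("motif patterns must be non-empty")


@dataclass
class MotifReport:
    """Scan result for one protein; positions are 1-based ungapped."""

    sequence_id: str
    dicysteine_found: bool
    dicysteine_positions: tuple[int, int] | None
    plc_found: bool
    plc_tyrosine_position: int | None
    plc_context_class: str          # glycine | acidic | other | absent
    grb2_positions: list[int]
    pip_found: bool
    pip_position: int | None
    proline_fraction: float
    docking_conserved: dict[int, bool] = field(default_factory=dict)


def motif_scan(protein: SequenceRecord, config: MotifConfig | None = None,
               msa: MSA | None = None, ref_id: str | None = None,
               docking_positions: tuple[int, ...] = (),
               ) -> MotifReport:
    """Scan one protein for the configured motif panel.

    When an MSA containing both the protein and a reference row is supplied,
    the proline region and the docking-tyrosine conservation flags are
    evaluated in reference numbering mapped through the alignment; otherwise
    the raw interval is used and no conservation flags are produced.
    """
    config = config or MotifConfig()
    seq = protein.residues

    # palmitoylation pair, restricted to the N-terminal window
    lo, hi = config.dicysteine_window
    window_seq = seq[lo - 1:hi]
    m = re.search(config.dicysteine_pattern, window_seq)
    if m:
        first = lo + m.start()
        second = lo + m.end() - 1
        dicys_found, dicys_pos = True, (first, second)
    else:
        dicys_found, dicys_pos = False, None

    m = re.search(config.plc_pattern, seq)
    if m:
        plc_found = True
        ty = m.start() + 1
        before = seq[m.start() - 1] if m.start() > 0 else ""
        if before == "G":
            context = "glycine"
        elif before in ("D", "E"):
            context = "acidic"
        else:
            context = "other"
    else:
        plc_found, ty, context = False, None, "absent"

    grb2 = [m.start() + 1
            for m in re.finditer(f"(?=({config.grb2_pattern}))", seq)]

    m = re.search(config.lck_motif, seq)
    pip_found = m is not None
    pip_pos = m.start() + 1 if m else None

    rlo, rhi = config.proline_region
    use_msa = (msa is not None and ref_id is not None
               and protein.id in msa.ids)
    if use_msa:
        start_map = map_ref_position(msa, ref_id, rlo)[protein.id]
        end_map = map_ref_position(msa, ref_id, rhi)[protein.id]
        # fall back to raw bounds when the mapped endpoint is a gap
        start = start_map[1] if start_map[1] is not None else rlo
        end = end_map[1] if end_map[1] is not None else rhi
    else:
        start, end = rlo, rhi
    start = max(1, start)
    end = min(len(seq), end)
    region = seq[start - 1:end]
    proline_fraction = region.count("P") / len(region) if region else 0.0

    docking: dict[int, bool] = {}
    if use_msa and docking_positions:
        for pos in docking_positions:
            residue, _ = map_ref_position(msa, ref_id, pos)[protein.id]
            docking[pos] = residue == "Y"

    return MotifReport(
        sequence_id=protein.id,
        dicysteine_found=dicys_found,
        dicysteine_positions=dicys_pos,
        plc_found=plc_found,
        plc_tyrosine_position=ty,
        plc_context_class=context,
        grb2_positions=grb2,
        pip_found=pip_found,
        pip_position=pip_pos,
        proline_fraction=proline_fraction,
        docking_conserved=docking,
    )
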