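"""Run configuration: a flat key=value file plus command-line overrides.

Every stochastic operation receives an explicit seed (default 42).  Keys use
dots for grouping; ``immune.<tissue>=true|false`` builds the tissue->immune
map for the expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .recruit import ScoringScheme

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


@dataclass
class RunConfig:
    seed: int = 42
    # recruitment scoring
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    k_const: float = 0.46
    bit_threshold: float = 100.0
    word_size: int = 11
    # assembly
    min_overlap: int = 30
    max_mismatch_rate: float = 0.02
    max_rounds: int = 5
    min_aa: int = 50
    # GC metrics
    min_stretch_len: int = 3
    min_cds_length: int = 300
    # simulation
    target_gc: float = 0.72
    read_length: int = 100
    error_rate: float = 0.01
    # expression
    immune: dict[str, bool] = field(default_factory=dict)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(match=self.match, mismatch=self.mismatch,
                             gap_open=self.gap_open, gap_extend=self.gap_extend,
                             lam=self.lam, k_const=self.k_const,
                             bit_threshold=self.bit_threshold,
                             word_size=self.word_size)


def load_config(path: str | Path | None = None,
                overrides: dict[str, str] | None = None) -> RunConfig:
    """Build a RunConfig from an optional key=value file and overrides."""
    cfg = RunConfig()
    items: list[tuple[str, str]] = []
    if path is not None:
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key=value): {line!r}")
            key, value = line.split("=", 1)
            items.append((key.strip(), value.strip()))
    for key, value in (overrides or {}).items():
        items.append((key, value))

    known = {f.name: f.type for f in fields(RunConfig) if f.name != "immune"}
    for key, value in items:
        if key.startswith("immune."):
            tissue = key[len("immune."):]
            flag = _BOOL.get(value.lower())
            if flag is None and value.lower() in ("immune", "non-immune"):
                flag = value.lower() == "immune"
            if flag is None:
                raise ValueError(f"bad immune flag for {tissue!r}: {value!r}")
            cfg.immune[tissue] = flag
            continue
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        caster = type(current)
        setattr(cfg, key, caster(value))
    return cfg
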