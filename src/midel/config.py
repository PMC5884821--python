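"""Caller configuration with the documented defaults.

Thresholds named ``min_*`` are exclusive where the filter is strict (mapping
quality > 20, clip length > 5, clip mean base quality > 20) and inclusive
otherwise (supporting depth >= 10, size bounds 50..10000 inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class CallerConfig:
    # read / clip filters (strict: value must exceed the threshold)
    min_mapq: int = 20
    min_clip_len: int = 5
    min_clip_meanq: float = 20.0
    use_duplicates: bool = False
    include_secondary: bool = False

    # insert-size model used to place unmapped reads
    insert_mean: int = 500
    insert_sd: int = 50

    # clustering
    cluster_tol_bp: int = 3
    rescue_tol_bp: int | None = None  # None -> insert_sd
    linkage: str = "chain"  # or "span"

    # consensus / assembly
    msa_mode: str = "internal"  # or "external" (MAFFT-compatible binary)
    min_members: int = 2
    k: int = 25
    min_kmer_count: int = 2

    # glocal alignment scores
    match: int = 5
    mismatch: int = -20
    gap_open: int = -20
    gap_extend: int = 0

    # pairing / joining
    max_span: int = 10_000
    overlap_slack: int = 200
    min_join_overlap: int = 20
    min_join_identity: float = 0.9
    join_ctx: int = 150

    # calling
    flank: int = 5_000
    min_size: int = 50
    max_size: int = 10_000
    min_depth: int = 10
    hom_vaf: float = 0.8

    def __post_init__(self) -> None:
        if self.linkage not in ("chain", "span"):
            raise ValueError(f"linkage must be 'chain' or 'span', got {self.linkage!r}")
        if self.msa_mode not in ("internal", "external"):
            raise ValueError(f"msa_mode must be 'internal' or 'external', got {self.msa_mode!r}")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    @property
    def effective_rescue_tol(self) -> int:
        return self.insert_sd if self.rescue_tol_bp is None else self.rescue_tol_bp

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallerConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
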