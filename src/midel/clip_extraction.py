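"""Read classification and soft-clip fragment extraction.

Reads are sorted into high-quality soft-clipped reads, unmapped reads with a
mapped mate, plain mapped reads, and discards (duplicates, fully unmapped
pairs).  Soft-clip filters are strict: mapping quality > 20, clip length > 5
and clip mean base quality > 20; the minimum passing clip is therefore 6 bp.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

from midel.core_io import AlignedRead, REF_CONSUMING

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ReadClass(enum.Enum):
    HQ_SOFTCLIPPED = "HQ_SOFTCLIPPED"
    UNMAPPED_WITH_MATE = "UNMAPPED_WITH_MATE"
    MAPPED = "MAPPED"
    DISCARDED = "DISCARDED"


FWD = "FWD"
BWD = "BWD"


@dataclass
class ClippedFragment:
    """One soft-clipped tail with its breakpoint on the reference axis.

    ``FWD``: the clip hangs off the right/3' end of the aligned part and the
    clipped sequence extends rightward from ``breakpoint0``.  ``BWD``: the clip
    hangs off the left/5' end and extends leftward, ending at ``breakpoint0``.
    """

    chrom: str
    breakpoint0: int
    orientation: str
    seq: str
    quals: Sequence[int]
    source_read: str
    mapq: int

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("clip sequence/quality length mismatch")
        if self.orientation not in (FWD, BWD):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class UnmappedMate:
    """An unmapped read placed near its mapped mate via the insert-size model."""

    seq: str
    quals: Sequence[int]
    anchor_chrom: str
    anchor_pos0: int
    anchor_is_reverse: bool
    est_breakpoint0: int
    est_orientation: str
    source_read: str = ""


def _mean_qual(quals: Sequence[int]) -> float:
    return sum(quals) / len(quals) if len(quals) else 0.0


def _clip_segments(read: AlignedRead) -> list[tuple[str, int, int]]:
    """Soft-clip segments as (side, query_start, query_end).

    side is 'L' for a leading clip, 'R' for a trailing clip.  Hard clips carry
    no sequence and are ignored as fragment sources.
    """
    cigar = [cg for cg in read.cigar if cg[0] != "H"]
    if not cigar:
        return []
    segments = []
    qpos = 0
    for i, (op, n) in enumerate(cigar):
        if op == "S":
            side = "L" if i == 0 else "R"
            segments.append((side, qpos, qpos + n))
        if op in "MIS=X":
            qpos += n
    return segments


def _passing_clips(
    read: AlignedRead, min_clip_len: int, min_clip_meanq: float
) -> list[tuple[str, int, int]]:
    out = []
    for side, qs, qe in _clip_segments(read):
        if qe - qs > min_clip_len and _mean_qual(read.quals[qs:qe]) > min_clip_meanq:
            out.append((side, qs, qe))
    return out


def classify_read(
    read: AlignedRead,
    min_mapq: int = 20,
    min_clip_len: int = 5,
    min_clip_meanq: float = 20.0,
    use_duplicates: bool = False,
) -> ReadClass:
    """Classify one read.  Total function: never raises.

    ``HQ_SOFTCLIPPED`` requires a mapped, non-duplicate read with mapping
    quality strictly above ``min_mapq`` and at least one soft-clip segment of
    length strictly above ``min_clip_len`` whose mean base quality is strictly
    above ``min_clip_meanq``.
    """
    if read.is_duplicate and not use_duplicates:
        return ReadClass.DISCARDED
    if read.is_unmapped:
        if read.mate_is_unmapped:
            return ReadClass.DISCARDED
        return ReadClass.UNMAPPED_WITH_MATE
    if read.mapq > min_mapq and _passing_clips(read, min_clip_len, min_clip_meanq):
        return ReadClass.HQ_SOFTCLIPPED
    return ReadClass.MAPPED


def extract_clips(
    read: AlignedRead,
    min_mapq: int = 20,
    min_clip_len: int = 5,
    min_clip_meanq: float = 20.0,
) -> list[ClippedFragment]:
    """Extract the passing clipped fragments of a high-quality soft-clipped read.

    A trailing clip (``...xM yS``) yields a FWD fragment whose breakpoint is
    the first clipped position on the reference axis, i.e. ``pos0`` plus the
    reference-consumed length of the aligned part.  A leading clip
    (``yS xM...``) yields a BWD fragment at ``pos0``.  Sub-threshold clip
    segments are dropped individually; a read clipped at both ends can yield
    two fragments.
    """
    cls = classify_read(read, min_mapq, min_clip_len, min_clip_meanq)
    if cls is not ReadClass.HQ_SOFTCLIPPED:
        raise ValueError(
            f"extract_clips requires an HQ_SOFTCLIPPED read, got {cls.value}"
        )
    ref_span = sum(n for op, n in read.cigar if op in REF_CONSUMING)
    fragments = []
    for side, qs, qe in _passing_clips(read, min_clip_len, min_clip_meanq):
        if side == "L":
            orientation, breakpoint0 = BWD, read.pos0
        else:
            orientation, breakpoint0 = FWD, read.pos0 + ref_span
        fragments.append(
            ClippedFragment(
                chrom=read.chrom,
                breakpoint0=breakpoint0,
                orientation=orientation,
                seq=read.seq[qs:qe],
                quals=list(read.quals[qs:qe]),
                source_read=read.query_name,
                mapq=read.mapq,
            )
        )
    fragments.sort(key=lambda f: (f.breakpoint0, f.orientation))
    return fragments


def estimate_unmapped_breakpoint(
    um: AlignedRead,
    insert_mean: int,
    insert_sd: int,
    mate_ref_span: int | None = None,
) -> UnmappedMate:
    """Place an unmapped read using its mapped mate and the insert-size model.

    With a forward-strand anchor the unmapped read lies downstream:
    ``est_breakpoint0 = anchor_pos0 + insert_mean - read_length`` (FWD).  With
    a reverse-strand anchor it lies upstream:
    ``est_breakpoint0 = anchor_pos0 - insert_mean + read_length + mate_ref_span``
    (BWD).  The stored sequence is flipped onto the reference forward strand
    (an unmapped read is stored as sequenced; in forward-anchor pairs it is the
    reverse-strand member).

    ``mate_ref_span`` defaults to the unmapped read's own length.
    """
    if not um.is_unmapped:
        raise ValueError("read is mapped; nothing to estimate")
    if um.mate_is_unmapped:
        raise ValueError("mate is unmapped; no anchor available")
    read_length = len(um.seq)
    span = mate_ref_span if mate_ref_span is not None else read_length
    if not um.mate_is_reverse:
        est = um.mate_pos0 + insert_mean - read_length
        orientation = FWD
        seq = revcomp(um.seq)
        quals = list(um.quals)[::-1]
    else:
        est = um.mate_pos0 - insert_mean + read_length + span
        orientation = BWD
        seq = um.seq
        quals = list(um.quals)
    if est < 0:
        warnings.warn(
            f"estimated breakpoint {est} for {um.query_name!r} clamped to 0",
            stacklevel=2,
        )
        est = 0
    return UnmappedMate(
        seq=seq,
        quals=quals,
        anchor_chrom=um.mate_chrom,
        anchor_pos0=um.mate_pos0,
        anchor_is_reverse=um.mate_is_reverse,
        est_breakpoint0=est,
        est_orientation=orientation,
        source_read=um.query_name,
    )
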