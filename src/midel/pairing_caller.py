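"""Glocal alignment, consensus-fragment pairing/joining and indel extraction.

The aligner is global in the query (every query base must be aligned) and
local in the target (leading/trailing target bases are free), matching the
semantics of a global-in-query library search.  Scoring is affine: a gap of
length k costs ``gap_open + k * gap_extend``.  The defaults (+5 match, -20
mismatch, -20 open, 0 extend) make long indels cost a single gap opening, so
a multi-kilobase deletion aligns as one gap instead of a mismatch wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from midel.clip_extraction import BWD, FWD, revcomp
from midel.clustering import BreakpointCluster
from midel.core_io import IndelCall, ReferenceWindow

NEG = -(10**9)


@dataclass
class GlocalParams:
    match: int = 5
    mismatch: int = -20
    gap_open: int = -20
    gap_extend: int = 0

    def __post_init__(self) -> None:
        if self.mismatch >= 0:
            raise ValueError("mismatch must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class GlocalResult:
    score: int
    query_aln: str
    target_aln: str
    target_start: int
    target_end: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def glocal_align(query: str, target: str, p: GlocalParams | None = None) -> GlocalResult:
    """Align ``query`` globally against the best-scoring window of ``target``.

    Dynamic programming over three states: H (match/mismatch), F (query base
    against a target gap, "up") and E (target base against a query gap,
    "left").  Traceback ties prefer diagonal, then up, then left.  The
    reported target window ends at the rightmost maximal-scoring end column,
    so a final query base prefers a diagonal (mismatch) step over an end gap.
    """
    if p is None:
        p = GlocalParams()
    if not query or not target:
        raise ValueError("glocal_align requires nonempty sequences")
    q = _encode(query)
    t = _encode(target)
    n, m = len(q), len(t)
    go, ge, ma, mi = p.gap_open, p.gap_extend, p.match, p.mismatch

    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, :] = 0
    rows = np.arange(1, n + 1, dtype=np.int64)
    H[1:, 0] = go + ge * rows
    F[1:, 0] = go + ge * rows

    cols = np.arange(m + 1, dtype=np.int64)
    ext_cols = ge * cols
    for i in range(1, n + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] + ge, H[i - 1, 1:] + go + ge)
        sub = np.where(t == q[i - 1], ma, mi)
        diag = H[i - 1, :-1] + sub
        df = np.maximum(diag, F[i, 1:])
        # E[i, j] = go + ge*j + max_{k<j}(H[i, k] - ge*k); since go <= 0 the
        # running max of H - ge*k is achieved by diagonal/vertical entries.
        a = np.empty(m + 1, dtype=np.int64)
        a[0] = H[i, 0]
        a[1:] = df - ext_cols[1:]
        g = np.maximum.accumulate(a)
        E[i, 1:] = go + ext_cols[1:] + g[:-1]
        H[i, 1:] = np.maximum(df, E[i, 1:])

    j = m - int(np.argmax(H[n, ::-1]))  # rightmost maximal end column
    score = int(H[n, j])
    target_end = j

    q_parts: list[str] = []
    t_parts: list[str] = []
    i = n
    state = "H"
    while True:
        if state == "H":
            if i == 0:
                break
            if j > 0 and H[i, j] == H[i - 1, j - 1] + (ma if q[i - 1] == t[j - 1] else mi):
                q_parts.append(query[i - 1])
                t_parts.append(target[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP bookkeeping is exhaustive
                raise AssertionError("traceback stuck")
        elif state == "F":
            q_parts.append(query[i - 1])
            t_parts.append("-")
            if F[i, j] == H[i - 1, j] + go + ge:
                state = "H"
            i -= 1
        else:  # E
            q_parts.append("-")
            t_parts.append(target[j - 1])
            if E[i, j] == H[i, j - 1] + go + ge:
                state = "H"
            j -= 1
    target_start = j
    return GlocalResult(
        score=score,
        query_aln="".join(reversed(q_parts)),
        target_aln="".join(reversed(t_parts)),
        target_start=target_start,
        target_end=target_end,
    )


# ---------------------------------------------------------------------------
# pairing and joining of consensus fragments
# ---------------------------------------------------------------------------


@dataclass
class ConsensusSequence:
    """The joined FWD+BWD consensus spanning the whole event."""

    seq: str
    fwd_ref: "object"  # ConsensusFragment (import cycle avoided)
    bwd_ref: "object"
    junction_offset: int
    depth: int
    join_score: int = 0
    start0: int = -1  # reference coordinate where the joined sequence starts


def pair_clusters(
    fwd: Sequence["object"],
    bwd: Sequence["object"],
    max_span: int = 10_000,
    overlap_slack: int = 200,
) -> list[tuple["object", "object"]]:
    """Candidate (FWD, BWD) consensus-fragment pairs.

    A pair is a candidate iff ``-overlap_slack <= b.breakpoint0 -
    f.breakpoint0 <= max_span``: deletions put the BWD breakpoint downstream
    of the FWD one by the deleted length; insertions have near-coincident
    breakpoints.  A fragment may appear in several candidates; the caller
    resolves overlaps greedily by join score.
    """
    pairs = []
    for f in fwd:
        for b in bwd:
            span = b.breakpoint0 - f.breakpoint0
            if -overlap_slack <= span <= max_span:
                pairs.append((f, b))
    pairs.sort(key=lambda fb: (fb[0].breakpoint0, fb[1].breakpoint0))
    return pairs


def _overlap_merge(
    left: str,
    right: str,
    p: GlocalParams,
    min_overlap: int,
    min_identity: float,
) -> tuple[int, int] | None:
    """Best suffix(left)/prefix(right) overlap by alignment score.

    Returns (overlap_length, score) or None when no overlap of at least
    ``min_overlap`` bases reaches ``min_identity``.
    """
    la = _encode(left)
    ra = _encode(right)
    best: tuple[int, int] | None = None
    max_o = min(len(left), len(right))
    for o in range(min_overlap, max_o + 1):
        matches = int(np.count_nonzero(la[len(la) - o :] == ra[:o]))
        if matches / o < min_identity:
            continue
        score = matches * p.match + (o - matches) * p.mismatch
        if best is None or score > best[1]:
            best = (o, score)
    return best


def join_pair(
    f: "object",
    b: "object",
    p: GlocalParams,
    ref_seq: Callable[[str, int, int], str],
    ctx: int = 150,
    min_join_overlap: int = 20,
    min_join_identity: float = 0.9,
) -> ConsensusSequence | None:
    """Join a FWD/BWD consensus-fragment pair into one spanning sequence.

    Each fragment is extended with its anchoring reference context: the FWD
    fragment gets ``ctx`` reference bases prepended upstream of its breakpoint,
    the BWD fragment gets ``ctx`` bases appended downstream.  The two extended
    sequences must overlap by at least ``min_join_overlap`` bases at >=
    ``min_join_identity`` identity; the merged sequence is the union through
    the overlap.

    ``ref_seq(chrom, start0, end0)`` supplies reference sequence.
    """
    ctx_f = min(ctx, f.breakpoint0)
    ext_f = ref_seq(f.chrom, f.breakpoint0 - ctx_f, f.breakpoint0).upper() + f.seq
    ext_b = b.seq + ref_seq(b.chrom, b.breakpoint0, b.breakpoint0 + ctx).upper()
    hit = _overlap_merge(ext_f, ext_b, p, min_join_overlap, min_join_identity)
    if hit is None:
        return None
    overlap, score = hit
    merged = ext_f + ext_b[overlap:]
    depth = len(f.source_reads | b.source_reads)
    return ConsensusSequence(
        seq=merged,
        fwd_ref=f,
        bwd_ref=b,
        junction_offset=len(ext_f),
        depth=depth,
        join_score=score,
        start0=f.breakpoint0 - ctx_f,
    )


def select_joined(joined: Iterable[ConsensusSequence]) -> list[ConsensusSequence]:
    """Greedy disjoint selection: each fragment used once, best join score first."""
    used: set[int] = set()
    kept = []
    for cs in sorted(
        joined, key=lambda c: (-c.join_score, c.fwd_ref.breakpoint0, c.bwd_ref.breakpoint0)
    ):
        fid, bid = id(cs.fwd_ref), id(cs.bwd_ref)
        if fid in used or bid in used:
            continue
        used.add(fid)
        used.add(bid)
        kept.append(cs)
    kept.sort(key=lambda c: c.fwd_ref.breakpoint0)
    return kept


# ---------------------------------------------------------------------------
# indel extraction
# ---------------------------------------------------------------------------


def genotype_call(
    n_variant_support: int, n_reference_spanning: int, hom_vaf: float = 0.8
) -> str:
    """het/hom from the variant allele fraction; hom iff VAF >= ``hom_vaf``."""
    if n_variant_support < 1:
        raise ValueError("genotype_call requires at least one supporting read")
    v = n_variant_support / (n_variant_support + n_reference_spanning)
    return "hom" if v >= hom_vaf else "het"


def call_indels(
    cs: ConsensusSequence,
    ref: ReferenceWindow,
    p: GlocalParams | None = None,
    min_size: int = 50,
    max_size: int = 10_000,
    min_depth: int = 10,
    spanning_counter: Callable[[str, int], int] | None = None,
    hom_vaf: float = 0.8,
    min_align_identity: float = 0.9,
    junction_margin: int = 300,
    max_calls_per_consensus: int = 2,
) -> list[IndelCall]:
    """Extract size/depth-filtered indels from consensus vs reference window.

    The joined consensus is the query (global), the window the target (local).
    A run of gap columns in the query row deletes reference bases (DEL); a run
    in the target row inserts consensus bases (INS).  Candidates survive iff
    ``min_size <= L <= max_size`` and supporting depth >= ``min_depth``.

    Alignments whose matched (non-gap) columns fall below
    ``min_align_identity`` identity are rejected wholesale: they indicate a
    chimeric or misplaced consensus, and their gap runs are noise.  Candidate
    gap runs must also start within ``junction_margin`` query bases of the
    fragment-join column: the paired clip evidence only supports an event at
    the junction, and gap runs elsewhere come from chimeric joins.  For the
    same reason an alignment producing more than ``max_calls_per_consensus``
    size-passing candidates is treated as a chimeric join and yields nothing.
    """
    if p is None:
        p = GlocalParams()
    res = glocal_align(cs.seq, ref.seq, p)
    aligned_cols = matched_cols = 0
    for qc, tc in zip(res.query_aln, res.target_aln):
        if qc != "-" and tc != "-":
            aligned_cols += 1
            if qc == tc:
                matched_cols += 1
    if aligned_cols == 0 or matched_cols / aligned_cols < min_align_identity:
        return []
    calls: list[IndelCall] = []
    n_size_passing = 0
    ref_pos = ref.start0 + res.target_start  # 0-based next reference base
    qpos = 0
    i = 0
    qa, ta = res.query_aln, res.target_aln
    ncols = len(qa)
    while i < ncols:
        near_junction = abs(qpos - cs.junction_offset) <= junction_margin
        if qa[i] == "-":  # deletion: reference consumed, consensus gapped
            j = i
            while j < ncols and qa[j] == "-":
                j += 1
            length = j - i
            deleted = ta[i:j]
            if min_size <= length <= max_size:
                n_size_passing += 1
            if near_junction:
                _maybe_call(
                    calls, cs, ref, "DEL", ref_pos, length, "", deleted,
                    min_size, max_size, min_depth, spanning_counter, hom_vaf,
                )
            ref_pos += length
            i = j
        elif ta[i] == "-":  # insertion: consensus consumed, reference gapped
            j = i
            while j < ncols and ta[j] == "-":
                j += 1
            length = j - i
            inserted = qa[i:j]
            if min_size <= length <= max_size:
                n_size_passing += 1
            if near_junction:
                _maybe_call(
                    calls, cs, ref, "INS", ref_pos, length, inserted, "",
                    min_size, max_size, min_depth, spanning_counter, hom_vaf,
                )
            qpos += length
            i = j
        else:
            ref_pos += 1
            qpos += 1
            i += 1
    if n_size_passing > max_calls_per_consensus:
        return []
    return calls


def _maybe_call(
    calls: list[IndelCall],
    cs: ConsensusSequence,
    ref: ReferenceWindow,
    svtype: str,
    ref_pos0: int,
    length: int,
    inserted: str,
    deleted: str,
    min_size: int,
    max_size: int,
    min_depth: int,
    spanning_counter: Callable[[str, int], int] | None,
    hom_vaf: float,
) -> None:
    if not (min_size <= length <= max_size):
        return
    if cs.depth < min_depth:
        return
    n_span = spanning_counter(ref.chrom, ref_pos0) if spanning_counter else 0
    calls.append(
        IndelCall(
            chrom=ref.chrom,
            pos1=ref_pos0,  # 0-based event start == 1-based anchor position
            svtype=svtype,
            length=length,
            alt_seq=inserted,
            ref_span=deleted,
            depth=cs.depth,
            genotype=genotype_call(cs.depth, n_span, hom_vaf),
            breakpoint_fwd=cs.fwd_ref.breakpoint0,
            breakpoint_bwd=cs.bwd_ref.breakpoint0,
        )
    )
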