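"""End-to-end orchestration: alignments + reference in, indel calls out."""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

from midel.clip_extraction import (
    BWD,
    FWD,
    ClippedFragment,
    ReadClass,
    UnmappedMate,
    classify_read,
    estimate_unmapped_breakpoint,
    extract_clips,
)
from midel.clustering import attach_unmapped, cluster_fragments
from midel.config import CallerConfig
from midel.consensus import assemble_unmapped, build_consensus, merge_contigs
from midel.core_io import AlignedRead, IndelCall, fetch_reference_window, read_alignments
from midel.pairing_caller import (
    GlocalParams,
    call_indels,
    join_pair,
    pair_clusters,
    select_joined,
)


class _SpanIndex:
    """Mapped-read intervals used to count reference-spanning reads."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int, tuple[int, ...]]] = []

    def add(self, read: AlignedRead) -> None:
        clips = []
        cigar = [cg for cg in read.cigar if cg[0] != "H"]
        if cigar and cigar[0][0] == "S":
            clips.append(read.pos0)
        if cigar and cigar[-1][0] == "S":
            clips.append(read.reference_end0)
        self.intervals.append((read.pos0, read.reference_end0, tuple(clips)))

    def count_spanning(self, pos0: int, margin: int = 20, clip_tol: int = 3) -> int:
        n = 0
        for start, end, clips in self.intervals:
            if start + margin <= pos0 <= end - margin and not any(
                abs(c - pos0) <= clip_tol for c in clips
            ):
                n += 1
        return n


def _params(cfg: CallerConfig) -> GlocalParams:
    return GlocalParams(
        match=cfg.match,
        mismatch=cfg.mismatch,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )


def call_chromosome(
    reads: Iterable[AlignedRead],
    chrom: str,
    fasta: Fasta,
    cfg: CallerConfig,
) -> list[IndelCall]:
    """Run the full caller on the reads of one chromosome."""
    params = _params(cfg)
    frags: list[ClippedFragment] = []
    rescued: list[UnmappedMate] = []
    spans = _SpanIndex()
    for read in reads:
        cls = classify_read(
            read,
            min_mapq=cfg.min_mapq,
            min_clip_len=cfg.min_clip_len,
            min_clip_meanq=cfg.min_clip_meanq,
            use_duplicates=cfg.use_duplicates,
        )
        if cls is ReadClass.DISCARDED:
            continue
        if cls is ReadClass.UNMAPPED_WITH_MATE:
            if read.mate_chrom in ("", "=") or read.mate_chrom == chrom:
                rescued.append(
                    estimate_unmapped_breakpoint(read, cfg.insert_mean, cfg.insert_sd)
                )
            continue
        spans.add(read)
        if cls is ReadClass.HQ_SOFTCLIPPED:
            frags.extend(
                extract_clips(
                    read,
                    min_mapq=cfg.min_mapq,
                    min_clip_len=cfg.min_clip_len,
                    min_clip_meanq=cfg.min_clip_meanq,
                )
            )
    clusters = cluster_fragments(frags, tol=cfg.cluster_tol_bp, linkage=cfg.linkage)
    clusters, pooled = attach_unmapped(clusters, rescued, tol=cfg.effective_rescue_tol)
    fragments = []
    for cluster in clusters:
        frag = build_consensus(
            cluster,
            min_members=cfg.min_members,
            msa_mode=cfg.msa_mode,
            params=params,
        )
        if frag is not None:
            fragments.append(frag)
    if pooled:
        contigs = assemble_unmapped(pooled, k=cfg.k, min_kmer_count=cfg.min_kmer_count)
        if contigs:
            fragments = merge_contigs(fragments, contigs, params)
    fwd = [f for f in fragments if f.orientation == FWD]
    bwd = [f for f in fragments if f.orientation == BWD]

    def ref_seq(c: str, start0: int, end0: int) -> str:
        return str(fasta[c][max(0, start0) : end0])

    joined = []
    for f, b in pair_clusters(fwd, bwd, cfg.max_span, cfg.overlap_slack):
        cs = join_pair(
            f,
            b,
            params,
            ref_seq,
            ctx=cfg.join_ctx,
            min_join_overlap=cfg.min_join_overlap,
            min_join_identity=cfg.min_join_identity,
        )
        if cs is not None:
            joined.append(cs)
    calls: list[IndelCall] = []
    for cs in select_joined(joined):
        window = fetch_reference_window(
            fasta, chrom, cs.fwd_ref.breakpoint0, flank=cfg.flank
        )
        calls.extend(
            call_indels(
                cs,
                window,
                params,
                min_size=cfg.min_size,
                max_size=cfg.max_size,
                min_depth=cfg.min_depth,
                spanning_counter=lambda c, p0: spans.count_spanning(p0),
                hom_vaf=cfg.hom_vaf,
            )
        )
    # dedupe identical events reachable through different fragment pairs
    best: dict[tuple, IndelCall] = {}
    for call in calls:
        key = (call.chrom, call.pos1, call.svtype, call.length)
        if key not in best or call.depth > best[key].depth:
            best[key] = call
    out = sorted(best.values(), key=lambda c: (c.chrom, c.pos1, c.svtype))
    return out


def call_sample(
    aln_path: str | Path,
    ref_path: str | Path,
    cfg: CallerConfig | None = None,
    region: str | None = None,
) -> list[IndelCall]:
    """Call intermediate-size indels on a whole SAM/BAM file."""
    cfg = cfg or CallerConfig()
    fasta = Fasta(str(ref_path))
    by_chrom: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in read_alignments(aln_path, region=region, include_secondary=cfg.include_secondary):
        chrom = read.chrom if not read.is_unmapped else (read.mate_chrom or read.chrom)
        if not chrom:
            continue
        by_chrom[chrom].append(read)
    calls: list[IndelCall] = []
    for chrom in sorted(by_chrom):
        if chrom not in fasta:
            continue
        calls.extend(call_chromosome(by_chrom[chrom], chrom, fasta, cfg))
    calls.sort(key=lambda c: (c.chrom, c.pos1, c.svtype))
    return calls
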