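"""Per-cluster consensus building and greedy k-mer assembly of unmapped reads.

A cluster's member sequences are multiple-aligned (internal star alignment by
default, or an external MAFFT-compatible binary) and summarised column-wise by
majority vote.  Unattached unmapped reads are assembled into contigs with a
greedy highest-count k-mer extender; a contig replaces a cluster's consensus
fragment when the fragment is contained in it at high identity, which is how
insertions longer than a single clipped tail get reconstructed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from midel.clip_extraction import BWD, FWD, UnmappedMate, revcomp
from midel.clustering import BreakpointCluster
from midel.pairing_caller import GlocalParams, glocal_align

MAFFT_ARGS = ["--nuc", "--ep", "0.0", "--op", "1", "--genafpair", "--maxiterate", "1000"]


@dataclass
class ConsensusFragment:
    cluster_ref: BreakpointCluster | None
    seq: str
    depth_per_col: list[int]
    depth: int
    orientation: str
    chrom: str
    breakpoint0: int
    source_reads: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.depth_per_col):
            raise ValueError("consensus sequence/depth length mismatch")
        if "-" in self.seq:
            raise ValueError("consensus sequence contains gap characters")


@dataclass
class Contig:
    seq: str
    kmer_size: int
    n_reads: int
    read_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.seq) < self.kmer_size:
            raise ValueError("contig shorter than its k-mer size")


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------


def msa(
    seqs: Sequence[str],
    mode: str = "internal",
    params: GlocalParams | None = None,
) -> list[str]:
    """Multiple-align sequences; returns equal-length gapped rows in input order.

    Internal mode is a star alignment: the longest sequence is the center,
    every other sequence is aligned to it with the glocal DP and the pairwise
    alignments are merged under "once a gap, always a gap".  External mode
    shells out to a MAFFT-compatible binary.
    """
    if len(seqs) < 2:
        raise ValueError("msa requires at least two sequences")
    if mode == "external":
        return _msa_external(seqs)
    if mode != "internal":
        raise ValueError(f"unknown msa mode {mode!r}")
    return _msa_star(seqs, params or GlocalParams())


def _msa_external(seqs: Sequence[str]) -> list[str]:
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError(
            "no MAFFT-compatible binary on PATH; use msa_mode='internal'"
        )
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fa"
        fin.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        proc = subprocess.run(
            [exe, *MAFFT_ARGS, str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: dict[str, list[str]] = {}
    name = ""
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            rows[name] = []
        elif name:
            rows[name].append(line.strip())
    return ["".join(rows[f"s{i}"]).upper() for i in range(len(seqs))]


def _msa_star(seqs: Sequence[str], params: GlocalParams) -> list[str]:
    m_center = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    center = seqs[m_center]
    m = len(center)
    # per row: aligned char for each center position (None = not covered,
    # '-' = deletion relative to center) and inserted runs keyed by slot.
    aligned: list[list[str | None]] = []
    inserts: list[dict[int, str]] = []
    for idx, s in enumerate(seqs):
        if idx == m_center:
            aligned.append(list(center))
            inserts.append({})
            continue
        res = glocal_align(s, center, params)
        row: list[str | None] = [None] * m
        ins: dict[int, str] = {}
        c = res.target_start
        for qc, tc in zip(res.query_aln, res.target_aln):
            if tc == "-":
                ins[c] = ins.get(c, "") + qc
            else:
                row[c] = qc  # qc may be '-' (gap vs center)
                c += 1
        aligned.append(row)
        inserts.append(ins)
    slot_width = [0] * (m + 1)
    for ins in inserts:
        for c, run in ins.items():
            slot_width[c] = max(slot_width[c], len(run))
    out_rows: list[str] = []
    for row, ins in zip(aligned, inserts):
        parts: list[str] = []
        for c in range(m + 1):
            run = ins.get(c, "")
            parts.append(run + "-" * (slot_width[c] - len(run)))
            if c < m:
                ch = row[c]
                parts.append(ch if ch is not None else "-")
        out_rows.append("".join(parts))
    assert len({len(r) for r in out_rows}) == 1
    return out_rows


# ---------------------------------------------------------------------------
# consensus voting
# ---------------------------------------------------------------------------


def _vote_columns(
    rows: Sequence[str], quals: Sequence[Sequence[int]]
) -> tuple[str, list[int]]:
    """Column-wise majority vote over aligned rows.

    Leading/trailing gaps of a row mark positions the sequence does not reach
    and cast no vote; internal gaps vote for a gap.  Columns where gaps hold a
    strict majority of the covering rows are deleted.  Ties between bases go
    to the larger summed base quality, then lexicographically.
    """
    ncols = len(rows[0])
    extents = []
    qidx: list[list[int | None]] = []
    for r in rows:
        first = next((i for i, ch in enumerate(r) if ch != "-"), ncols)
        last = next((i for i in range(ncols - 1, -1, -1) if r[i] != "-"), -1)
        extents.append((first, last))
        pos = 0
        idx_map: list[int | None] = []
        for ch in r:
            if ch == "-":
                idx_map.append(None)
            else:
                idx_map.append(pos)
                pos += 1
        qidx.append(idx_map)
    out_seq: list[str] = []
    out_depth: list[int] = []
    for col in range(ncols):
        votes: Counter[str] = Counter()
        qual_sum: Counter[str] = Counter()
        gap_votes = 0
        covered = 0
        for ri, r in enumerate(rows):
            first, last = extents[ri]
            if col < first or col > last:
                continue
            covered += 1
            ch = r[col]
            if ch == "-":
                gap_votes += 1
            else:
                votes[ch] += 1
                k = qidx[ri][col]
                qual_sum[ch] += quals[ri][k] if k is not None else 0
        if covered == 0 or gap_votes > covered / 2:
            continue
        if not votes:
            continue
        best = max(votes, key=lambda b: (votes[b], qual_sum[b], -ord(b[0])))
        # lexicographic tie-break: smaller base wins, hence -ord
        out_seq.append(best)
        out_depth.append(sum(votes.values()))
    return "".join(out_seq), out_depth


def build_consensus(
    cluster: BreakpointCluster,
    min_members: int = 2,
    msa_mode: str = "internal",
    params: GlocalParams | None = None,
    min_consensus_len: int = 6,
) -> ConsensusFragment | None:
    """Build one majority-vote consensus fragment for a cluster.

    Member sequences (clipped fragments plus rescued unmapped reads) are
    anchored at the breakpoint — FWD left-aligned, BWD right-aligned — and
    multiple-aligned.  Returns None when fewer than ``min_members`` sequences
    are available or the consensus ends up shorter than ``min_consensus_len``.
    """
    seqs = [m.seq for m in cluster.members] + [r.seq for r in cluster.rescued]
    quals = [list(m.quals) for m in cluster.members] + [
        list(r.quals) for r in cluster.rescued
    ]
    if len(seqs) < min_members:
        return None
    flip = cluster.orientation == BWD
    if flip:  # right-anchor by reversing, then undo
        seqs = [s[::-1] for s in seqs]
        quals = [q[::-1] for q in quals]
    if len(seqs) == 1:
        cons, depth = seqs[0], [1] * len(seqs[0])
    else:
        rows = msa(seqs, mode=msa_mode, params=params)
        cons, depth = _vote_columns(rows, quals)
    if flip:
        cons = cons[::-1]
        depth = depth[::-1]
    if len(cons) < min_consensus_len:
        return None
    # The anchor coordinate of the consensus is the breakpoint of its
    # furthest-reaching member: microhomology at the junction shifts member
    # breakpoints by a few bases, the alignment absorbs the shift, and the
    # first (FWD) / last (BWD) consensus column belongs to the member with the
    # smallest / largest breakpoint.
    member_bps = [m.breakpoint0 for m in cluster.members]
    if member_bps:
        anchor_bp = min(member_bps) if cluster.orientation == FWD else max(member_bps)
    else:
        anchor_bp = cluster.breakpoint0
    return ConsensusFragment(
        cluster_ref=cluster,
        seq=cons,
        depth_per_col=depth,
        depth=max(depth),
        orientation=cluster.orientation,
        chrom=cluster.chrom,
        breakpoint0=anchor_bp,
        source_reads=cluster.source_reads(),
    )


# ---------------------------------------------------------------------------
# greedy k-mer assembly
# ---------------------------------------------------------------------------


def _canonical(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def assemble_unmapped(
    reads: Sequence[UnmappedMate | str],
    k: int = 25,
    min_kmer_count: int = 2,
) -> list[Contig]:
    """Greedy k-mer assembly of unmapped reads into contigs.

    All k-mers are counted with both strands canonicalised.  Repeatedly: seed
    on the most frequent unused k-mer, extend right then left one base at a
    time choosing the highest-count overlapping k-mer, stopping when the best
    extension drops below ``min_kmer_count`` or revisits a used k-mer.
    Contigs shorter than ``2*k`` are dropped; output is sorted by descending
    read support.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd to make canonical k-mers strand-unique")
    seq_of = lambda r: r if isinstance(r, str) else r.seq
    name_of = lambda i, r: f"read{i}" if isinstance(r, str) else (r.source_read or f"read{i}")
    counts: Counter[str] = Counter()
    for r in reads:
        s = seq_of(r).upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                counts[_canonical(km)] += 1
    used: set[str] = set()
    contigs: list[Contig] = []
    order = sorted(counts, key=lambda km: (-counts[km], km))
    for seed in order:
        if seed in used or counts[seed] < min_kmer_count:
            continue
        contig = seed
        used.add(seed)
        # extend right
        while True:
            nxt = _best_extension(contig[-(k - 1) :], counts, used, k, min_kmer_count, right=True)
            if nxt is None:
                break
            base, km = nxt
            contig += base
            used.add(km)
        # extend left
        while True:
            nxt = _best_extension(contig[: k - 1], counts, used, k, min_kmer_count, right=False)
            if nxt is None:
                break
            base, km = nxt
            contig = base + contig
            used.add(km)
        if len(contig) >= 2 * k:
            kmers = {
                _canonical(contig[i : i + k]) for i in range(len(contig) - k + 1)
            }
            names = {
                name_of(i, r)
                for i, r in enumerate(reads)
                if _shares_kmer(seq_of(r).upper(), kmers, k)
            }
            contigs.append(
                Contig(seq=contig, kmer_size=k, n_reads=len(names), read_names=names)
            )
    contigs.sort(key=lambda c: (-c.n_reads, -len(c.seq), c.seq))
    return contigs


def _shares_kmer(s: str, kmers: set[str], k: int) -> bool:
    return any(_canonical(s[i : i + k]) in kmers for i in range(len(s) - k + 1))


def _best_extension(
    core: str,
    counts: Counter,
    used: set[str],
    k: int,
    min_kmer_count: int,
    right: bool,
) -> tuple[str, str] | None:
    best: tuple[int, str, str] | None = None
    for base in "ACGT":
        km = core + base if right else base + core
        canon = _canonical(km)
        c = counts.get(canon, 0)
        if c < min_kmer_count or canon in used:
            continue
        if best is None or c > best[0]:
            best = (c, base, canon)
    if best is None:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# contig merge-back
# ---------------------------------------------------------------------------


def merge_contigs(
    fragments: Sequence[ConsensusFragment],
    contigs: Sequence[Contig],
    params: GlocalParams | None = None,
    min_identity: float = 0.9,
) -> list[ConsensusFragment]:
    """Replace consensus fragments contained in a contig by the contig.

    A contig (either strand) replaces a fragment when the fragment aligns
    within it end-to-end at >= ``min_identity`` identity and the replacement
    extends the fragment.  FWD fragments keep their left anchor (the contig
    part from the match start onward); BWD fragments keep their right anchor.
    """
    params = params or GlocalParams()
    out: list[ConsensusFragment] = []
    for frag in fragments:
        best: tuple[int, str, set[str]] | None = None
        for contig in contigs:
            for oriented in (contig.seq, revcomp(contig.seq)):
                if len(oriented) <= len(frag.seq):
                    continue
                res = glocal_align(frag.seq, oriented, params)
                matches = sum(
                    1 for a, b in zip(res.query_aln, res.target_aln) if a == b != "-"
                )
                if matches / len(frag.seq) < min_identity:
                    continue
                new_seq = (
                    oriented[res.target_start :]
                    if frag.orientation == FWD
                    else oriented[: res.target_end]
                )
                if len(new_seq) <= len(frag.seq):
                    continue
                if best is None or len(new_seq) > len(best[1]):
                    best = (matches, new_seq, contig.read_names)
        if best is None:
            out.append(frag)
        else:
            _, new_seq, names = best
            out.append(
                ConsensusFragment(
                    cluster_ref=frag.cluster_ref,
                    seq=new_seq,
                    depth_per_col=[frag.depth] * len(new_seq),
                    depth=frag.depth,
                    orientation=frag.orientation,
                    chrom=frag.chrom,
                    breakpoint0=frag.breakpoint0,
                    source_reads=frag.source_reads | names,
                )
            )
    return out
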