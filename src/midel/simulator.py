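"""Desk-scale simulation: toy reference, planted indels, paired-end reads and
an analytic (aligner-free) mapper.

The analytic mapper emits SAM records straight from simulation bookkeeping:
reads inside unaltered sequence get full-match CIGARs, reads crossing a
planted breakpoint get the soft-clip CIGAR an aligner would produce (the
longer collinear side anchors, the rest is clipped, and the anchor is greedily
extended through bases that happen to match the reference past the
breakpoint), and reads wholly inside a long insertion come out unmapped with
their mapped mate's coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from midel.clip_extraction import revcomp
from midel.evaluation import TruthRecord

BASES = "ACGT"
DEFAULT_QUAL = 35


@dataclass
class SimConfig:
    n_bins: int = 10
    bin_size: int = 10_000
    ref_length: int | None = None  # default: n_bins * bin_size
    indel_sizes: tuple[int, ...] = tuple(range(100, 1001, 100))
    n_ins: int = 5
    n_del: int = 5
    mutation_rate: float = 0.001
    read_length: int = 150
    coverage: float = 100.0
    base_error: float = 0.02
    outer_distance: int = 500
    outer_sd: int = 50
    seed: int = 1
    zygosity: str = "hom"  # "hom": all reads from the alt haplotype
    insert_mode: str = "random"  # or "flank": copy the downstream flank
    chrom: str = "sim"
    extend_matches: bool = True  # aligner-like extension through chance matches
    anchor_min: int = 20

    def __post_init__(self) -> None:
        if self.ref_length is None:
            self.ref_length = self.n_bins * self.bin_size
        if self.n_ins + self.n_del != self.n_bins:
            raise ValueError("n_ins + n_del must equal n_bins (one event per bin)")
        if self.bin_size <= max(self.indel_sizes) + 2 * self.read_length:
            raise ValueError("bin_size must exceed max indel size + 2 read lengths")
        for rate in (self.mutation_rate, self.base_error):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.read_length > self.outer_distance:
            raise ValueError("read_length must not exceed outer_distance")
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be 'hom' or 'het'")
        if self.insert_mode not in ("random", "flank"):
            raise ValueError("insert_mode must be 'random' or 'flank'")


@dataclass
class SimulatedPair:
    """One read pair with its fragment bookkeeping (alt-haplotype coords)."""

    chrom: str
    frag_start: int
    frag_end: int
    flip: int  # 0: read1 is the left/forward read; 1: swapped
    hap: int  # 1: alt haplotype, 0: reference haplotype
    index: int
    r1_seq: str
    r2_seq: str

    @property
    def qname(self) -> str:
        return (
            f"sim|{self.chrom}|{self.frag_start}|{self.frag_end}|"
            f"{self.flip}|{self.hap}|{self.index}"
        )

    @staticmethod
    def parse_qname(qname: str) -> tuple[str, int, int, int, int, int]:
        tag, chrom, fs, fe, flip, hap, idx = qname.split("|")
        if tag != "sim":
            raise ValueError(f"read {qname!r} has no simulation bookkeeping")
        return chrom, int(fs), int(fe), int(flip), int(hap), int(idx)


def random_reference(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Seeded i.i.d. ACGT toy reference."""
    arr = rng.integers(0, 4, size=cfg.ref_length)
    seq = "".join(BASES[i] for i in arr)
    return {cfg.chrom: seq}


def plant_indels(
    ref: dict[str, str], cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant one indel per selected 10 kb bin; return (alt genome, truth).

    Events are centred in their bin with +/-25% jitter.  Insertion sequences
    are i.i.d. uniform ACGT, or a copy of the downstream flank in
    ``insert_mode='flank'`` (reproducing the repetitive-insertion regime where
    greedy assembly and clip anchoring break down).
    """
    chrom = cfg.chrom
    seq = ref[chrom]
    total_bins = len(seq) // cfg.bin_size
    if cfg.n_bins > total_bins:
        raise ValueError(
            f"requested {cfg.n_bins} bins but reference holds only {total_bins}"
        )
    bins = sorted(rng.choice(total_bins, size=cfg.n_bins, replace=False).tolist())
    svtypes = ["DEL"] * cfg.n_del + ["INS"] * cfg.n_ins
    rng.shuffle(svtypes)
    sizes: dict[str, int] = {"DEL": 0, "INS": 0}
    truth: list[TruthRecord] = []
    for b, svtype in zip(bins, svtypes):
        length = cfg.indel_sizes[sizes[svtype] % len(cfg.indel_sizes)]
        sizes[svtype] += 1
        jitter = int(rng.integers(-cfg.bin_size // 4, cfg.bin_size // 4 + 1))
        p0 = b * cfg.bin_size + cfg.bin_size // 2 + jitter
        p0 = max(b * cfg.bin_size + cfg.read_length, min(p0, (b + 1) * cfg.bin_size - length - cfg.read_length))
        if svtype == "DEL":
            event_seq = seq[p0 : p0 + length]
        elif cfg.insert_mode == "flank":
            event_seq = seq[p0 : p0 + length]  # copy of the right flank
        else:
            event_seq = "".join(
                BASES[i] for i in rng.integers(0, 4, size=length)
            )
        truth.append(
            TruthRecord(
                chrom=chrom, pos1=p0, svtype=svtype, length=length, sequence=event_seq
            )
        )
    truth.sort(key=lambda t: t.pos1)
    alt_parts: list[str] = []
    cursor = 0
    for t in truth:
        p0 = t.pos1  # 0-based event start (pos1 is the 1-based anchor before it)
        alt_parts.append(seq[cursor:p0])
        if t.svtype == "DEL":
            cursor = p0 + t.length
        else:
            alt_parts.append(t.sequence)
            cursor = p0
    alt_parts.append(seq[cursor:])
    return {chrom: "".join(alt_parts)}, truth


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    lut = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    for i in hits:
        alts = lut.get(arr[i])
        if alts:
            arr[i] = alts[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def point_mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply haplotype point mutations once, before read sampling."""
    return _apply_errors(seq, rate, rng)


def simulate_reads(
    genome: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
    reference: dict[str, str] | None = None,
) -> list[SimulatedPair]:
    """Draw inward-facing read pairs with Normal(outer_distance, outer_sd)
    fragment sizes and per-base substitution errors.

    Point mutations (``mutation_rate``) are applied once to each haplotype
    before sampling.  In ``zygosity='het'`` mode half the fragments are drawn
    from the unmodified reference haplotype (``reference`` required).
    """
    if cfg.zygosity == "het" and reference is None:
        raise ValueError("het simulation requires the reference haplotype")
    rl = cfg.read_length
    pairs: list[SimulatedPair] = []
    for chrom, seq in genome.items():
        alt = point_mutate(seq, cfg.mutation_rate, rng)
        ref_hap = (
            point_mutate(reference[chrom], cfg.mutation_rate, rng)
            if cfg.zygosity == "het"
            else ""
        )
        glen = len(alt)
        n_pairs = int(cfg.coverage * glen / (2 * rl))
        for i in range(n_pairs):
            hap = 1 if cfg.zygosity == "hom" else int(rng.integers(0, 2))
            hap_seq = alt if hap == 1 else ref_hap
            hlen = len(hap_seq)
            flen = int(round(rng.normal(cfg.outer_distance, cfg.outer_sd)))
            flen = max(rl, min(flen, hlen))
            fs = int(rng.integers(0, hlen - flen + 1))
            fe = fs + flen
            left = _apply_errors(hap_seq[fs : fs + rl], cfg.base_error, rng)
            right = _apply_errors(revcomp(hap_seq[fe - rl : fe]), cfg.base_error, rng)
            flip = int(rng.integers(0, 2))
            r1, r2 = (right, left) if flip else (left, right)
            pairs.append(
                SimulatedPair(
                    chrom=chrom,
                    frag_start=fs,
                    frag_end=fe,
                    flip=flip,
                    hap=hap,
                    index=i,
                    r1_seq=r1,
                    r2_seq=r2,
                )
            )
    return pairs


def write_fastq(pairs: Sequence[SimulatedPair], out1: Path, out2: Path) -> None:
    q = chr(DEFAULT_QUAL + 33)
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.qname}/1\n{p.r1_seq}\n+\n{q * len(p.r1_seq)}\n")
            f2.write(f"@{p.qname}/2\n{p.r2_seq}\n+\n{q * len(p.r2_seq)}\n")


def read_fastq_pairs(fq1: Path, fq2: Path) -> list[SimulatedPair]:
    """Rebuild bookkeeping pairs from FASTQ written by :func:`write_fastq`."""

    def _records(path: Path) -> Iterable[tuple[str, str]]:
        lines = Path(path).read_text().splitlines()
        for i in range(0, len(lines), 4):
            yield lines[i][1:].rsplit("/", 1)[0], lines[i + 1]

    pairs = []
    for (n1, s1), (n2, s2) in zip(_records(fq1), _records(fq2)):
        if n1 != n2:
            raise ValueError(f"FASTQ mates out of sync: {n1!r} vs {n2!r}")
        chrom, fs, fe, flip, hap, idx = SimulatedPair.parse_qname(n1)
        pairs.append(
            SimulatedPair(
                chrom=chrom, frag_start=fs, frag_end=fe, flip=flip, hap=hap,
                index=idx, r1_seq=s1, r2_seq=s2,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# analytic mapping
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    m_start: int
    m_end: int
    ref_start: int | None  # None: inserted sequence, maps nowhere


def _alt_blocks(truth: Sequence[TruthRecord]) -> list[_Block]:
    """Collinear/insertion blocks of the alt haplotype against the reference."""
    blocks: list[_Block] = []
    r = 0
    m = 0
    for t in sorted(truth, key=lambda t: t.pos1):
        p0 = t.pos1
        if p0 > r:
            blocks.append(_Block(m, m + (p0 - r), r))
            m += p0 - r
            r = p0
        if t.svtype == "DEL":
            r += t.length
        else:
            blocks.append(_Block(m, m + t.length, None))
            m += t.length
    blocks.append(_Block(m, m + 10**12, r))  # open-ended tail
    return blocks


@dataclass
class _Mapping:
    mapped: bool
    pos0: int = -1
    left_clip: int = 0
    match_len: int = 0
    right_clip: int = 0

    @property
    def cigar(self) -> str:
        if not self.mapped:
            return "*"
        parts = []
        if self.left_clip:
            parts.append(f"{self.left_clip}S")
        parts.append(f"{self.match_len}M")
        if self.right_clip:
            parts.append(f"{self.right_clip}S")
        return "".join(parts)

    @property
    def ref_end0(self) -> int:
        return self.pos0 + self.match_len


def _map_read(
    s: int,
    e: int,
    fseq: str,
    blocks: Sequence[_Block],
    ref: str,
    extend_matches: bool,
) -> _Mapping:
    """Map read occupying alt coords [s, e) given its forward-strand sequence."""
    pieces: list[tuple[int, int, int | None]] = []  # (read_off, length, ref_pos)
    for b in blocks:
        if b.m_end <= s or b.m_start >= e:
            continue
        lo, hi = max(s, b.m_start), min(e, b.m_end)
        rp = None if b.ref_start is None else b.ref_start + (lo - b.m_start)
        pieces.append((lo - s, hi - lo, rp))
    mapped_pieces = [p for p in pieces if p[2] is not None]
    if not mapped_pieces:
        return _Mapping(mapped=False)
    anchor = max(mapped_pieces, key=lambda p: p[1])
    if anchor[1] <= 0:
        return _Mapping(mapped=False)
    off, mlen, rpos = anchor
    lc, rc = off, (e - s) - off - mlen
    if extend_matches:
        # extend like an aligner through chance matches past the breakpoint
        while rc > 0 and rpos + mlen < len(ref) and fseq[lc + mlen] == ref[rpos + mlen]:
            mlen += 1
            rc -= 1
        while lc > 0 and rpos > 0 and fseq[lc - 1] == ref[rpos - 1]:
            lc -= 1
            rpos -= 1
            mlen += 1
    return _Mapping(mapped=True, pos0=rpos, left_clip=lc, match_len=mlen, right_clip=rc)


def analytic_map(
    pairs: Sequence[SimulatedPair],
    ref: dict[str, str],
    truth: Sequence[TruthRecord],
    out_sam: str | Path,
    cfg: SimConfig | None = None,
) -> Path:
    """Write a coordinate-sorted SAM mapping simulated pairs analytically."""
    cfg = cfg or SimConfig()
    blocks_by_chrom = {c: _alt_blocks([t for t in truth if t.chrom == c]) for c in ref}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.items()],
        }
    )
    tid = {c: i for i, c in enumerate(ref)}
    records: list[pysam.AlignedSegment] = []
    for p in pairs:
        blocks = blocks_by_chrom[p.chrom]
        rl = len(p.r1_seq)
        # forward-strand coordinates of the two reads on their haplotype
        left_iv = (p.frag_start, p.frag_start + rl)
        right_iv = (p.frag_end - rl, p.frag_end)
        left_raw, right_raw = (p.r2_seq, p.r1_seq) if p.flip else (p.r1_seq, p.r2_seq)
        left_f = left_raw  # left read sequenced on the forward strand
        right_f = revcomp(right_raw)
        if p.hap == 1:
            lmap = _map_read(*left_iv, left_f, blocks, ref[p.chrom], cfg.extend_matches)
            rmap = _map_read(*right_iv, right_f, blocks, ref[p.chrom], cfg.extend_matches)
        else:  # reference haplotype: identity mapping
            lmap = _Mapping(True, left_iv[0], 0, rl, 0)
            rmap = _Mapping(True, right_iv[0], 0, rl, 0)
        for which, own, mate, fseq, raw, rev in (
            (1, lmap, rmap, left_f, left_raw, False),
            (2, rmap, lmap, right_f, right_raw, True),
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = p.qname
            is_read1 = (which == 1) != bool(p.flip)
            flag = 0x1
            flag |= 0x40 if is_read1 else 0x80
            if own.mapped:
                if rev:
                    flag |= 0x10
            else:
                flag |= 0x4
            if mate.mapped:
                if which == 1 and True:  # mate of read 1 is the right/reverse read
                    flag |= 0x20
            else:
                flag |= 0x8
            if which == 2 and mate.mapped:
                pass  # mate (left read) is forward: no 0x20
            if own.mapped and mate.mapped:
                flag |= 0x2
            a.flag = flag
            if own.mapped:
                a.reference_id = tid[p.chrom]
                a.reference_start = own.pos0
                a.mapping_quality = 60
                a.cigarstring = own.cigar
                a.query_sequence = fseq
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(DEFAULT_QUAL + 33) * rl
                )
            else:
                a.reference_id = tid[p.chrom] if mate.mapped else -1
                a.reference_start = mate.pos0 if mate.mapped else -1
                a.mapping_quality = 0
                a.query_sequence = raw  # unmapped reads stay as sequenced
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(DEFAULT_QUAL + 33) * len(raw)
                )
            if mate.mapped:
                a.next_reference_id = tid[p.chrom]
                a.next_reference_start = mate.pos0
            elif own.mapped:
                a.next_reference_id = tid[p.chrom]
                a.next_reference_start = own.pos0
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            if own.mapped and mate.mapped:
                outer = max(own.ref_end0, mate.ref_end0) - min(own.pos0, mate.pos0)
                a.template_length = outer if own.pos0 <= mate.pos0 else -outer
            records.append(a)
    records.sort(
        key=lambda r: (
            r.reference_id if r.reference_id >= 0 else 10**9,
            r.reference_start if r.reference_start >= 0 else 10**9,
        )
    )
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as f:
        for r in records:
            f.write(r)
    return out_sam


# ---------------------------------------------------------------------------
# one-call dataset generation
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: Sequence[TruthRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tsvtype\tlength\tsequence\n")
        for t in truth:
            fh.write(f"{t.chrom}\t{t.pos1}\t{t.svtype}\t{t.length}\t{t.sequence}\n")


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate ref.fa, truth.tsv, reads_1.fq, reads_2.fq and mapped.sam."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ref = random_reference(cfg, rng)
    alt, truth = plant_indels(ref, cfg, rng)
    pairs = simulate_reads(alt, cfg, rng, reference=ref)
    paths = {
        "ref": outdir / "ref.fa",
        "truth": outdir / "truth.tsv",
        "fq1": outdir / "reads_1.fq",
        "fq2": outdir / "reads_2.fq",
        "sam": outdir / "mapped.sam",
    }
    write_fasta(ref, paths["ref"])
    write_truth_tsv(truth, paths["truth"])
    write_fastq(pairs, paths["fq1"], paths["fq2"])
    analytic_map(pairs, ref, truth, paths["sam"], cfg)
    return paths
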