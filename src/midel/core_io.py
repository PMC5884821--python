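"""Alignment, reference and VCF I/O plus the shared coordinate conventions.

Internal coordinates are 0-based half-open everywhere; the single conversion
to 1-based coordinates happens in :func:`write_vcf`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pysam
from pyfaidx import Fasta

CIGAR_OPS = "MIDNSHP=X"
#: CIGAR operations that consume query bases.
QUERY_CONSUMING = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")


@dataclass
class AlignedRead:
    """One alignment record, decoupled from any particular file backend."""

    query_name: str
    chrom: str
    pos0: int
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: Sequence[int]
    is_unmapped: bool = False
    mate_is_unmapped: bool = False
    is_reverse: bool = False
    mate_is_reverse: bool = False
    is_duplicate: bool = False
    is_read1: bool = True
    mate_chrom: str = ""
    mate_pos0: int = -1
    template_length: int = 0

    def __post_init__(self) -> None:
        if self.seq and self.quals is not None and len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.query_name}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if self.seq and self.cigar:
            qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.query_name}: CIGAR consumes {qlen} query bases but "
                    f"sequence has {len(self.seq)}"
                )
        if not self.is_unmapped and self.pos0 < 0:
            raise ValueError(f"{self.query_name}: mapped read with negative position")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def reference_end0(self) -> int:
        return self.pos0 + self.reference_span


@dataclass
class ReferenceWindow:
    """A slice of the reference genome, 0-based half-open."""

    chrom: str
    start0: int
    end0: int
    seq: str

    def __post_init__(self) -> None:
        if self.end0 - self.start0 != len(self.seq):
            raise ValueError("window bounds inconsistent with sequence length")


@dataclass
class IndelCall:
    """A single called insertion or deletion.

    ``pos1`` is the 1-based position of the reference base immediately before
    the event, as placed in a VCF record.
    """

    chrom: str
    pos1: int
    svtype: str  # "INS" or "DEL"
    length: int
    alt_seq: str = ""
    ref_span: str = ""
    depth: int = 0
    genotype: str = "het"  # "het" or "hom"
    breakpoint_fwd: int = -1
    breakpoint_bwd: int = -1

    def __post_init__(self) -> None:
        if self.svtype not in ("INS", "DEL"):
            raise ValueError(f"svtype must be INS or DEL, got {self.svtype!r}")
        if self.svtype == "INS" and self.alt_seq and len(self.alt_seq) != self.length:
            raise ValueError("INS: alt_seq length disagrees with call length")
        if self.svtype == "DEL" and self.ref_span and len(self.ref_span) != self.length:
            raise ValueError("DEL: ref_span length disagrees with call length")


def _convert(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = (
        [(CIGAR_OPS[op], n) for op, n in rec.cigartuples] if rec.cigartuples else []
    )
    quals = list(rec.query_qualities) if rec.query_qualities is not None else []
    return AlignedRead(
        query_name=rec.query_name or "",
        chrom=rec.reference_name or "",
        pos0=rec.reference_start if not rec.is_unmapped else -1,
        mapq=rec.mapping_quality,
        cigar=cigar,
        seq=rec.query_sequence or "",
        quals=quals,
        is_unmapped=rec.is_unmapped,
        mate_is_unmapped=rec.mate_is_unmapped if rec.is_paired else True,
        is_reverse=rec.is_reverse,
        mate_is_reverse=rec.mate_is_reverse if rec.is_paired else False,
        is_duplicate=rec.is_duplicate,
        is_read1=not rec.is_read2,
        mate_chrom=rec.next_reference_name or "",
        mate_pos0=rec.next_reference_start,
        template_length=rec.template_length,
    )


def read_alignments(
    path: str | Path,
    region: str | None = None,
    include_secondary: bool = False,
) -> Iterator[AlignedRead]:
    """Stream alignment records from a SAM/BAM file.

    Records are yielded in file order (coordinate order for a sorted input).
    Duplicate-marked reads are yielded with their flag set; filtering them is
    the caller's business.  Secondary and supplementary alignments are skipped
    unless ``include_secondary`` is set.

    Parameters
    ----------
    path
        SAM or BAM file.  A ``region`` query requires an index.
    region
        Optional ``chrom`` or ``chrom:start-end`` (1-based, samtools style).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    save = pysam.set_verbosity(0)
    try:
        af = pysam.AlignmentFile(str(path), require_index=False)
    finally:
        pysam.set_verbosity(save)
    with af:
        if region is not None:
            if not af.has_index():
                raise ValueError(
                    f"region query {region!r} on {path} requires an index (.bai/.csi)"
                )
            it: Iterator[pysam.AlignedSegment] = af.fetch(region=region)
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if (rec.is_secondary or rec.is_supplementary) and not include_secondary:
                continue
            try:
                yield _convert(rec)
            except ValueError as exc:
                raise ValueError(f"malformed record {rec.query_name!r}: {exc}") from exc


def fetch_reference_window(
    fasta: str | Path | Fasta, chrom: str, breakpoint0: int, flank: int = 5000
) -> ReferenceWindow:
    """Return the upper-cased reference slice ``breakpoint0 +/- flank``.

    Bounds are clipped to ``[0, chromosome length]``.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    if chrom not in fa:
        raise KeyError(f"chromosome {chrom!r} not present in reference")
    chrom_len = len(fa[chrom])
    start0 = max(0, breakpoint0 - flank)
    end0 = min(chrom_len, breakpoint0 + flank)
    seq = str(fa[chrom][start0:end0]).upper()
    return ReferenceWindow(chrom=chrom, start0=start0, end0=end0, seq=seq)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant (INS or DEL)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the event; negative for deletions">
##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end position of the variant on REF">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: Sequence[IndelCall],
    ref: str | Path | Fasta,
    out: str | Path,
    sample: str = "SAMPLE",
) -> Path:
    """Write calls as a VCF 4.2 file with explicit REF/ALT sequences.

    DEL: REF = anchor base + deleted span, ALT = anchor base.
    INS: REF = anchor base, ALT = anchor base + inserted sequence.
    """
    fa = ref if isinstance(ref, Fasta) else Fasta(str(ref))
    out = Path(out)
    lines = [_VCF_HEADER.rstrip("\n")]
    for name in fa.keys():
        lines.append(f"##contig=<ID={name},length={len(fa[name])}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for call in calls:
        if call.chrom not in fa:
            raise KeyError(f"call chromosome {call.chrom!r} not in reference")
        chrom_len = len(fa[call.chrom])
        anchor0 = call.pos1 - 1
        if anchor0 < 0 or anchor0 >= chrom_len:
            raise ValueError(
                f"call at {call.chrom}:{call.pos1} outside reference ({chrom_len} bp)"
            )
        anchor = str(fa[call.chrom][anchor0]).upper()
        if call.svtype == "DEL":
            if anchor0 + 1 + call.length > chrom_len:
                raise ValueError(
                    f"deletion at {call.chrom}:{call.pos1} runs off the chromosome"
                )
            span = call.ref_span or str(
                fa[call.chrom][anchor0 + 1 : anchor0 + 1 + call.length]
            ).upper()
            ref_allele = anchor + span
            alt_allele = anchor
            svlen = -call.length
            end1 = call.pos1 + call.length
        else:
            ref_allele = anchor
            alt_allele = anchor + call.alt_seq
            svlen = call.length
            end1 = call.pos1
        gt = "1/1" if call.genotype == "hom" else "0/1"
        info = f"SVTYPE={call.svtype};SVLEN={svlen};END={end1};DP={call.depth}"
        lines.append(
            f"{call.chrom}\t{call.pos1}\t.\t{ref_allele}\t{alt_allele}\t.\tPASS\t"
            f"{info}\tGT\t{gt}"
        )
    out.write_text("\n".join(lines) + "\n")
    return out


def read_vcf(path: str | Path) -> list[IndelCall]:
    """Parse a VCF written by :func:`write_vcf` back into calls."""
    calls: list[IndelCall] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _id, ref_a, alt_a, _q, _f, info, _fmt, gt = line.split("\t")
        tags = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
        svtype = tags["SVTYPE"]
        length = abs(int(tags["SVLEN"]))
        calls.append(
            IndelCall(
                chrom=chrom,
                pos1=int(pos),
                svtype=svtype,
                length=length,
                alt_seq=alt_a[1:] if svtype == "INS" else "",
                ref_span=ref_a[1:] if svtype == "DEL" else "",
                depth=int(tags.get("DP", 0)),
                genotype="hom" if gt.strip() == "1/1" else "het",
            )
        )
    return calls


def read_truth_tsv(path: str | Path) -> list["TruthRecord"]:
    """Read a truth table: chrom, pos1, svtype, length, sequence (TSV)."""
    from midel.evaluation import TruthRecord

    records: list[TruthRecord] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "chrom":  # header
            continue
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected >=4 columns")
        records.append(
            TruthRecord(
                chrom=parts[0],
                pos1=int(parts[1]),
                svtype=parts[2],
                length=int(parts[3]),
                sequence=parts[4] if len(parts) > 4 else "",
            )
        )
    return records
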