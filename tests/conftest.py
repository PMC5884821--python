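from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pytest

from midel.core_io import AlignedRead


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def make_read(
    name: str = "r1",
    chrom: str = "chr1",
    pos0: int = 100,
    mapq: int = 60,
    cigar: str = "150M",
    seq: str | None = None,
    qual: int = 35,
    quals: list[int] | None = None,
    **kwargs,
) -> AlignedRead:
    ops = parse_cigar(cigar) if cigar else []
    qlen = sum(n for op, n in ops if op in "MIS=X")
    if seq is None:
        rng = random.Random(hash((name, cigar)) & 0xFFFF)
        seq = "".join(rng.choice("ACGT") for _ in range(qlen or 150))
    if quals is None:
        quals = [qual] * len(seq)
    return AlignedRead(
        query_name=name,
        chrom=chrom,
        pos0=pos0,
        mapq=mapq,
        cigar=ops,
        seq=seq,
        quals=quals,
        **kwargs,
    )


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_fasta(tmp_path: Path):
    """A 20 kb single-chromosome FASTA on disk."""
    r = random.Random(7)
    seq = "".join(r.choice("ACGT") for _ in range(20_000))
    path = tmp_path / "ref.fa"
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    return path, seq


def write_sam(path: Path, records: list[str], chroms: dict[str, int]) -> Path:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in chroms.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")
    return path


def sam_line(
    name: str,
    flag: int,
    chrom: str,
    pos1: int,
    mapq: int,
    cigar: str,
    seq: str,
    qual: int = 35,
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
) -> str:
    q = chr(qual + 33) * len(seq)
    return (
        f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t"
        f"{tlen}\t{seq}\t{q}"
    )
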