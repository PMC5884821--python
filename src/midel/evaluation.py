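"""Truth matching and precision / recall / F-measure.

precision = TP/(TP+FP), recall = TP/(TP+FN) and the F-measure is their
harmonic mean, 2PR/(P+R) = 2TP/(2TP+FP+FN).  Rounded values use half-up
rounding computed exactly from the integer counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

from midel.core_io import IndelCall


@dataclass
class TruthRecord:
    chrom: str
    pos1: int
    svtype: str
    length: int
    sequence: str = ""
    genotype: str = "hom"


@dataclass
class EvaluationCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        if math.isnan(x):
            return x
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Metrics:
    precision: float
    recall: float
    f_measure: float
    precision_rounded: float = field(default=math.nan)
    recall_rounded: float = field(default=math.nan)
    f_measure_rounded: float = field(default=math.nan)


def compute_metrics(c: EvaluationCounts, ndigits: int = 2) -> Metrics:
    """Exact metric arithmetic from TP/FP/FN counts.

    Undefined ratios (zero denominators) come back as NaN with a warning.
    """
    if c.TP + c.FP > 0:
        p: Fraction | float = Fraction(c.TP, c.TP + c.FP)
    else:
        warnings.warn("precision undefined: TP+FP == 0", stacklevel=2)
        p = math.nan
    if c.TP + c.FN > 0:
        r: Fraction | float = Fraction(c.TP, c.TP + c.FN)
    else:
        warnings.warn("recall undefined: TP+FN == 0", stacklevel=2)
        r = math.nan
    if isinstance(p, Fraction) and isinstance(r, Fraction) and p + r > 0:
        f: Fraction | float = Fraction(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    else:
        f = math.nan
    return Metrics(
        precision=float(p) if isinstance(p, Fraction) else p,
        recall=float(r) if isinstance(r, Fraction) else r,
        f_measure=float(f) if isinstance(f, Fraction) else f,
        precision_rounded=round_half_up(p, ndigits) if isinstance(p, Fraction) else p,
        recall_rounded=round_half_up(r, ndigits) if isinstance(r, Fraction) else r,
        f_measure_rounded=round_half_up(f, ndigits) if isinstance(f, Fraction) else f,
    )


def match_calls(
    calls: Sequence[IndelCall],
    truth: Sequence[TruthRecord],
    pos_tol: int = 10,
    len_tol: float = 0.1,
    genotype_strict: bool = False,
) -> EvaluationCounts:
    """One-to-one greedy matching of calls to truth records.

    A call matches a truth record iff same chromosome and svtype, position
    difference <= ``pos_tol`` bp, and length difference <= ``len_tol`` times
    the truth length.  Calls are processed in coordinate order and take the
    nearest unmatched eligible truth record.  With ``genotype_strict`` a
    matched pair only counts as TP when the genotypes agree (otherwise the
    call is an FP and the truth record remains an FN).
    """
    if pos_tol < 0 or len_tol < 0:
        raise ValueError("tolerances must be non-negative")
    unmatched = list(range(len(truth)))
    tp = fp = 0
    matched_truth: set[int] = set()
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos1, c.svtype, c.length)):
        best_i: int | None = None
        best_d: int | None = None
        for i in unmatched:
            t = truth[i]
            if t.chrom != call.chrom or t.svtype != call.svtype:
                continue
            d = abs(t.pos1 - call.pos1)
            if d > pos_tol:
                continue
            if abs(t.length - call.length) > len_tol * t.length:
                continue
            if best_d is None or d < best_d or (d == best_d and i < best_i):
                best_i, best_d = i, d
        if best_i is None:
            fp += 1
            continue
        t = truth[best_i]
        if genotype_strict and call.genotype != t.genotype:
            fp += 1
            continue
        unmatched.remove(best_i)
        matched_truth.add(best_i)
        tp += 1
    fn = len(truth) - len(matched_truth)
    return EvaluationCounts(TP=tp, FP=fp, FN=fn)


def recall_by_size(
    calls: Sequence[IndelCall],
    truth: Sequence[TruthRecord],
    pos_tol: int = 10,
    len_tol: float = 0.1,
) -> dict[int, dict[str, float]]:
    """Per-truth-size recall table (sizes as planted, e.g. 100..1000)."""
    out: dict[int, dict[str, float]] = {}
    for size in sorted({t.length for t in truth}):
        sub = [t for t in truth if t.length == size]
        c = match_calls(calls, sub, pos_tol=pos_tol, len_tol=len_tol)
        out[size] = {
            "n": len(sub),
            "tp": c.TP,
            "recall": c.TP / len(sub) if sub else math.nan,
        }
    return out


def ratio(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact count ratio, rounded half-up (e.g. deletions / all indels)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(Fraction(numerator, denominator), ndigits)
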