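"""Breakpoint clustering of clipped fragments and rescue of unmapped reads.

Fragments of one orientation sharing a breakpoint within 3 bp are grouped.
The default linkage chains: a fragment joins the open cluster iff its
breakpoint is within tolerance of the previous member's breakpoint, so a
chain can span more than the tolerance overall.  ``linkage="span"`` instead
bounds the whole cluster span by the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from midel.clip_extraction import BWD, FWD, ClippedFragment, UnmappedMate


@dataclass
class BreakpointCluster:
    chrom: str
    orientation: str
    breakpoint0: int
    members: list[ClippedFragment] = field(default_factory=list)
    rescued: list[UnmappedMate] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.members) + len(self.rescued)

    def source_reads(self) -> set[str]:
        names = {m.source_read for m in self.members}
        names |= {r.source_read for r in self.rescued if r.source_read}
        return names


def _representative(breakpoints: list[int]) -> int:
    """Member median, lower of the two middles on even counts."""
    s = sorted(breakpoints)
    return s[(len(s) - 1) // 2]


def cluster_fragments(
    frags: list[ClippedFragment],
    tol: int = 3,
    linkage: str = "chain",
) -> list[BreakpointCluster]:
    """Group same-orientation fragments sharing a breakpoint within ``tol`` bp.

    Output clusters are sorted by (breakpoint0, orientation) with FWD before
    BWD.  The result is invariant to input order.
    """
    if linkage not in ("chain", "span"):
        raise ValueError(f"unknown linkage {linkage!r}")
    chroms = {f.chrom for f in frags}
    if len(chroms) > 1:
        raise ValueError(f"fragments span multiple chromosomes: {sorted(chroms)}")
    clusters: list[BreakpointCluster] = []
    for orientation in (FWD, BWD):
        sub = sorted(
            (f for f in frags if f.orientation == orientation),
            key=lambda f: (f.breakpoint0, f.source_read, f.seq),
        )
        open_members: list[ClippedFragment] = []
        for frag in sub:
            if open_members:
                anchor = (
                    open_members[-1].breakpoint0
                    if linkage == "chain"
                    else open_members[0].breakpoint0
                )
                if frag.breakpoint0 - anchor <= tol:
                    open_members.append(frag)
                    continue
                clusters.append(_finish(open_members))
            open_members = [frag]
        if open_members:
            clusters.append(_finish(open_members))
    clusters.sort(key=lambda c: (c.breakpoint0, 0 if c.orientation == FWD else 1))
    return clusters


def _finish(members: list[ClippedFragment]) -> BreakpointCluster:
    return BreakpointCluster(
        chrom=members[0].chrom,
        orientation=members[0].orientation,
        breakpoint0=_representative([m.breakpoint0 for m in members]),
        members=list(members),
    )


def attach_unmapped(
    clusters: list[BreakpointCluster],
    rescued: list[UnmappedMate],
    tol: int,
) -> tuple[list[BreakpointCluster], list[UnmappedMate]]:
    """Attach each rescued read to its nearest same-orientation cluster.

    A read attaches to at most one cluster, the nearest one within ``tol`` bp
    of its estimated breakpoint (ties go to the smaller coordinate).  Reads
    that attach nowhere are returned as a pool for de novo assembly.
    """
    pooled: list[UnmappedMate] = []
    by_orient: dict[str, list[BreakpointCluster]] = {FWD: [], BWD: []}
    for c in clusters:
        by_orient[c.orientation].append(c)
    for o in by_orient:
        by_orient[o].sort(key=lambda c: c.breakpoint0)
    for um in rescued:
        candidates = by_orient.get(um.est_orientation, [])
        best: BreakpointCluster | None = None
        best_dist: int | None = None
        for c in candidates:
            dist = abs(um.est_breakpoint0 - c.breakpoint0)
            if dist <= tol and (best_dist is None or dist < best_dist):
                best, best_dist = c, dist  # first hit at a distance wins: smaller coord
        if best is None:
            pooled.append(um)
        else:
            best.rescued.append(um)
    return clusters, pooled
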