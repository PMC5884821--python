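import itertools
import random

import pytest

from midel.clip_extraction import BWD, FWD, ClippedFragment, revcomp
from midel.clustering import BreakpointCluster
from midel.consensus import ConsensusFragment, build_consensus
from midel.core_io import ReferenceWindow
from midel.pairing_caller import (
    ConsensusSequence,
    GlocalParams,
    call_indels,
    genotype_call,
    glocal_align,
    join_pair,
    pair_clusters,
    select_joined,
)
from tests.conftest import random_seq


# --------------------------------------------------------------------------
# independent scoring oracle: full affine global alignment of the query
# against t[s:], taking the best end column, maximised over all starts s
# --------------------------------------------------------------------------


def nw_best_prefix(q: str, t: str, p: GlocalParams) -> int:
    """Affine global alignment of q vs every prefix of t; best end score."""
    NEG = -(10**8)
    n, m = len(q), len(t)
    go, ge = p.gap_open, p.gap_extend
    H = [0] + [go + ge * j for j in range(1, m + 1)]
    E = [NEG] + [go + ge * j for j in range(1, m + 1)]
    F = [NEG] * (m + 1)
    for i in range(1, n + 1):
        new_H = [go + ge * i] + [0] * m
        new_E = [NEG] * (m + 1)
        new_F = [new_H[0]] + [0] * m
        for j in range(1, m + 1):
            new_E[j] = max(new_E[j - 1] + ge, new_H[j - 1] + go + ge)
            new_F[j] = max(F[j] + ge, H[j] + go + ge)
            s = p.match if q[i - 1] == t[j - 1] else p.mismatch
            new_H[j] = max(H[j - 1] + s, new_E[j], new_F[j])
        H, E, F = new_H, new_E, new_F
    return max(H)


def oracle_glocal_score(q: str, t: str, p: GlocalParams) -> int:
    return max(nw_best_prefix(q, t[s:], p) for s in range(len(t)))


PARAM_SETS = [
    GlocalParams(),
    GlocalParams(match=2, mismatch=-3, gap_open=-5, gap_extend=-2),
    GlocalParams(match=1, mismatch=-1, gap_open=-1, gap_extend=0),
]


class TestGlocalAlign:
    def test_perfect_match(self):
        res = glocal_align("ACGTACGT", "ACGTACGT")
        assert res.score == 40
        assert "-" not in res.query_aln + res.target_aln

    def test_local_in_target(self):
        res = glocal_align("ACGT", "TTTTACGTTTTT")
        assert res.score == 20
        assert (res.target_start, res.target_end) == (4, 8)

    def test_long_query_gap_costs_one_open(self):
        res = glocal_align("ACGTACGT", "ACGTTTTTTTTTTTTACGT")
        assert res.score == 8 * 5 - 20
        assert res.query_aln.count("-") == 11

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            glocal_align("", "ACGT")
        with pytest.raises(ValueError):
            glocal_align("ACGT", "")

    def test_alignment_strings_consistent(self, rng):
        for _ in range(50):
            q = random_seq(rng, rng.randrange(1, 30))
            t = random_seq(rng, rng.randrange(1, 60))
            p = rng.choice(PARAM_SETS)
            res = glocal_align(q, t, p)
            assert res.query_aln.replace("-", "") == q
            assert res.target_aln.replace("-", "") == t[res.target_start : res.target_end]
            score = 0
            run = None
            for a, b in zip(res.query_aln, res.target_aln):
                if a == "-" or b == "-":
                    kind = "q" if a == "-" else "t"
                    if run != kind:
                        score += p.gap_open
                        run = kind
                    score += p.gap_extend
                else:
                    run = None
                    score += p.match if a == b else p.mismatch
            assert score == res.score

    def test_matches_oracle_random_pairs(self, rng):
        for _ in range(500):
            q = random_seq(rng, rng.randrange(1, 13))
            t = random_seq(rng, rng.randrange(1, 13))
            p = rng.choice(PARAM_SETS)
            assert glocal_align(q, t, p).score == oracle_glocal_score(q, t, p)

    def test_matches_oracle_exhaustive_small(self):
        p = GlocalParams()
        seqs = [
            "".join(s)
            for n in range(1, 5)
            for s in itertools.product("AC", repeat=n)
        ]
        for q in seqs:
            for t in seqs:
                assert glocal_align(q, t, p).score == oracle_glocal_score(q, t, p)

    def test_score_symmetric_under_reverse_complement(self, rng):
        for _ in range(100):
            q = random_seq(rng, rng.randrange(1, 20))
            t = random_seq(rng, rng.randrange(1, 40))
            p = rng.choice(PARAM_SETS)
            assert (
                glocal_align(q, t, p).score
                == glocal_align(revcomp(q), revcomp(t), p).score
            )


# --------------------------------------------------------------------------
# pairing / joining
# --------------------------------------------------------------------------


def make_fragment(bp, orientation, seq, depth=12, chrom="chr1", reads=None):
    return ConsensusFragment(
        cluster_ref=None,
        seq=seq,
        depth_per_col=[depth] * len(seq),
        depth=depth,
        orientation=orientation,
        chrom=chrom,
        breakpoint0=bp,
        source_reads=reads or {f"{orientation}{bp}_{i}" for i in range(depth)},
    )


class TestPairClusters:
    def test_deletion_like_pair(self):
        f = make_fragment(1000, FWD, "A" * 30)
        b = make_fragment(1060, BWD, "A" * 30)
        assert pair_clusters([f], [b]) == [(f, b)]

    def test_insertion_like_pair(self):
        f = make_fragment(1000, FWD, "A" * 30)
        b = make_fragment(1002, BWD, "A" * 30)
        assert pair_clusters([f], [b]) == [(f, b)]

    def test_bwd_slightly_upstream_allowed_by_slack(self):
        f = make_fragment(1000, FWD, "A" * 30)
        b = make_fragment(950, BWD, "A" * 30)
        assert pair_clusters([f], [b]) == [(f, b)]

    def test_span_beyond_max_rejected(self):
        f = make_fragment(1000, FWD, "A" * 30)
        b = make_fragment(20_000, BWD, "A" * 30)
        assert pair_clusters([f], [b]) == []


class TestJoinPair:
    def _ref(self, seq):
        return lambda chrom, s, e: seq[s:e]

    def test_deletion_join(self, rng):
        ref = random_seq(rng, 3000)
        del_start, del_len = 1000, 300
        f = make_fragment(del_start, FWD, ref[del_start + del_len : del_start + del_len + 70])
        b = make_fragment(del_start + del_len, BWD, ref[del_start - 70 : del_start])
        cs = join_pair(f, b, GlocalParams(), self._ref(ref))
        assert cs is not None
        # merged sequence is the sample junction: ...ref[:1000] + ref[1300:]...
        expected = ref[del_start - 150 : del_start] + ref[del_start + del_len : del_start + del_len + 150]
        assert cs.seq == expected
        assert cs.depth == len(f.source_reads | b.source_reads)

    def test_low_identity_overlap_rejected(self, rng):
        ref = random_seq(rng, 2000)
        tail = random_seq(rng, 40)
        head = list(tail)
        for i in range(0, 40, 5):  # 80% identity
            head[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[head[i]]
        f = make_fragment(1000, FWD, tail)
        b = make_fragment(1002, BWD, "".join(head))
        # context sequences are unrelated, only the clip overlap could join
        assert join_pair(f, b, GlocalParams(), self._ref(ref), ctx=0) is None

    def test_no_overlap_returns_none(self, rng):
        ref = random_seq(rng, 2000)
        f = make_fragment(1000, FWD, random_seq(rng, 60))
        b = make_fragment(1001, BWD, random_seq(rng, 60))
        assert join_pair(f, b, GlocalParams(), self._ref(ref), ctx=0) is None

    def test_select_joined_is_disjoint(self, rng):
        ref = random_seq(rng, 5000)
        f1 = make_fragment(1000, FWD, ref[1300:1370])
        b1 = make_fragment(1300, BWD, ref[930:1000])
        b2 = make_fragment(1303, BWD, ref[933:1000])
        joined = [
            j
            for j in (
                join_pair(f1, b1, GlocalParams(), self._ref(ref)),
                join_pair(f1, b2, GlocalParams(), self._ref(ref)),
            )
            if j
        ]
        kept = select_joined(joined)
        assert len(kept) == 1


# --------------------------------------------------------------------------
# indel extraction
# --------------------------------------------------------------------------


def window_of(seq, start0=0, chrom="chr1"):
    return ReferenceWindow(chrom=chrom, start0=start0, end0=start0 + len(seq), seq=seq)


def consensus_of(seq, depth=12, junction=None, fwd_bp=0, bwd_bp=0):
    f = make_fragment(fwd_bp, FWD, "ACGTACGTAC", depth=depth)
    b = make_fragment(bwd_bp, BWD, "ACGTACGTAC", depth=depth)
    return ConsensusSequence(
        seq=seq, fwd_ref=f, bwd_ref=b,
        junction_offset=len(seq) // 2 if junction is None else junction,
        depth=depth,
    )


class TestCallIndels:
    def test_planted_deletion_called(self, rng):
        ref = random_seq(rng, 2400)
        cs = consensus_of(ref[:1000] + ref[1060:], depth=12)
        calls = call_indels(cs, window_of(ref), min_depth=10)
        assert len(calls) == 1
        c = calls[0]
        assert (c.svtype, c.pos1, c.length) == ("DEL", 1000, 60)
        assert c.ref_span == ref[1000:1060]

    def test_planted_insertion_called(self, rng):
        ref = random_seq(rng, 2400)
        ins = random_seq(rng, 80)
        cs = consensus_of(ref[:1200] + ins + ref[1200:], junction=1200)
        calls = call_indels(cs, window_of(ref))
        assert len(calls) == 1
        c = calls[0]
        assert (c.svtype, c.pos1, c.length, c.alt_seq) == ("INS", 1200, 80, ins)

    def test_below_min_size_no_call(self, rng):
        ref = random_seq(rng, 2400)
        cs = consensus_of(ref[:1000] + ref[1049:])
        assert call_indels(cs, window_of(ref)) == []

    def test_below_min_depth_no_call(self, rng):
        ref = random_seq(rng, 2400)
        cs = consensus_of(ref[:1000] + ref[1060:], depth=9)
        assert call_indels(cs, window_of(ref)) == []

    def test_window_offset_converts_coordinates(self, rng):
        ref = random_seq(rng, 2400)
        cs = consensus_of(ref[:1000] + ref[1060:])
        calls = call_indels(cs, window_of(ref, start0=5000))
        assert calls[0].pos1 == 6000

    def test_depth_monotonicity(self, rng):
        ref = random_seq(rng, 2400)
        cs = consensus_of(ref[:1000] + ref[1060:], depth=15)
        n_calls = [
            len(call_indels(cs, window_of(ref), min_depth=d)) for d in range(10, 20)
        ]
        assert all(a >= b for a, b in zip(n_calls, n_calls[1:]))

    def test_roundtrip_random_planted_deletions(self, rng):
        ref = random_seq(rng, 12_000)
        for _ in range(50):
            L = rng.randrange(50, 5001)
            pos = rng.randrange(600, 11_000 - L - 600)
            lo = max(0, pos - 500)
            hi = min(len(ref), pos + L + 500)
            cs = consensus_of(ref[lo:pos] + ref[pos + L : hi], junction=pos - lo)
            calls = call_indels(cs, window_of(ref))
            assert len(calls) == 1
            c = calls[0]
            assert (c.svtype, c.length) == ("DEL", L)
            # the call may sit a few bases off when the junction is ambiguous
            # (microhomology); the edited sequences must agree exactly
            assert abs(c.pos1 - pos) <= 10
            assert ref[: c.pos1] + ref[c.pos1 + L :] == ref[:pos] + ref[pos + L :]

    def test_chimeric_alignment_yields_nothing(self, rng):
        # a consensus made of three distant reference pieces: many gap runs
        ref = random_seq(rng, 9000)
        cs = consensus_of(
            ref[500:900] + ref[2000:2400] + ref[4000:4400] + ref[6000:6400],
            junction=400,
        )
        assert call_indels(cs, window_of(ref)) == []


class TestGenotypeCall:
    def test_all_variant_is_hom(self):
        assert genotype_call(12, 0) == "hom"

    def test_balanced_is_het(self):
        assert genotype_call(12, 13) == "het"

    def test_vaf_boundary_inclusive(self):
        assert genotype_call(16, 4) == "hom"

    def test_no_support_rejected(self):
        with pytest.raises(ValueError):
            genotype_call(0, 5)
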