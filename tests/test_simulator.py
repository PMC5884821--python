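import numpy as np
import pytest

from midel.clip_extraction import revcomp
from midel.simulator import (
    SimConfig,
    SimulatedPair,
    analytic_map,
    plant_indels,
    point_mutate,
    random_reference,
    read_fastq_pairs,
    simulate_dataset,
    simulate_reads,
    write_fastq,
)
from midel.core_io import read_alignments, read_truth_tsv


def small_cfg(**kw):
    defaults = dict(n_bins=4, n_del=2, n_ins=2, indel_sizes=(100, 200),
                    coverage=30, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = SimConfig()
        assert cfg.ref_length == cfg.n_bins * cfg.bin_size

    def test_bin_size_must_fit_events(self):
        with pytest.raises(ValueError):
            SimConfig(bin_size=1200, indel_sizes=(1000,), read_length=150)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SimConfig(base_error=1.0)

    def test_read_length_vs_outer_distance(self):
        with pytest.raises(ValueError):
            SimConfig(read_length=600, outer_distance=500)

    def test_event_count_must_match_bins(self):
        with pytest.raises(ValueError):
            SimConfig(n_bins=10, n_ins=3, n_del=3)


class TestPlantIndels:
    def test_one_truth_record_per_bin(self):
        cfg = SimConfig(n_bins=10, n_del=5, n_ins=5)
        rng = np.random.default_rng(0)
        ref = random_reference(cfg, rng)
        _, truth = plant_indels(ref, cfg, rng)
        assert len(truth) == 10
        assert sum(t.svtype == "DEL" for t in truth) == 5

    def test_sizes_cycle_through_catalogue(self):
        cfg = SimConfig(n_bins=10, n_del=10, n_ins=0)
        rng = np.random.default_rng(0)
        _, truth = plant_indels(random_reference(cfg, rng), cfg, rng)
        assert sorted(t.length for t in truth) == list(range(100, 1001, 100))

    def test_deletion_conservation(self):
        cfg = small_cfg()
        rng = np.random.default_rng(1)
        ref = random_reference(cfg, rng)
        alt, truth = plant_indels(ref, cfg, rng)
        expected = sum(t.length for t in truth if t.svtype == "INS") - sum(
            t.length for t in truth if t.svtype == "DEL"
        )
        assert len(alt["sim"]) - len(ref["sim"]) == expected

    def test_deletion_flanks_identical_to_reference(self):
        cfg = small_cfg(n_del=4, n_ins=0, indel_sizes=(500,))
        rng = np.random.default_rng(2)
        ref = random_reference(cfg, rng)
        alt, truth = plant_indels(ref, cfg, rng)
        t = truth[0]
        assert alt["sim"][: t.pos1] == ref["sim"][: t.pos1]

    def test_flank_mode_copies_downstream_flank(self):
        cfg = small_cfg(n_del=0, n_ins=4, insert_mode="flank")
        rng = np.random.default_rng(3)
        ref = random_reference(cfg, rng)
        _, truth = plant_indels(ref, cfg, rng)
        for t in truth:
            assert t.sequence == ref["sim"][t.pos1 : t.pos1 + t.length]

    def test_too_many_bins_rejected(self):
        cfg = small_cfg()
        rng = np.random.default_rng(0)
        ref = {"sim": random_reference(cfg, rng)["sim"][: 2 * cfg.bin_size]}
        with pytest.raises(ValueError):
            plant_indels(ref, cfg, rng)


class TestSimulateReads:
    def test_pair_count_arithmetic(self):
        cfg = SimConfig(n_bins=10, n_del=5, n_ins=5, coverage=100, read_length=150)
        genome = {"sim": "ACGT" * 25_000}  # 100 kb
        rng = np.random.default_rng(0)
        pairs = simulate_reads(genome, cfg, rng)
        assert len(pairs) == 33_333

    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_cfg(base_error=0.0, mutation_rate=0.0)
        rng = np.random.default_rng(4)
        genome = random_reference(cfg, rng)
        pairs = simulate_reads(genome, cfg, rng)
        g = genome["sim"]
        for p in pairs[:200]:
            left, right = (p.r2_seq, p.r1_seq) if p.flip else (p.r1_seq, p.r2_seq)
            assert left == g[p.frag_start : p.frag_start + len(left)]
            assert revcomp(right) == g[p.frag_end - len(right) : p.frag_end]

    def test_determinism_byte_identical_fastq(self, tmp_path):
        cfg = small_cfg()
        for run in ("a", "b"):
            rng = np.random.default_rng(cfg.seed)
            genome = random_reference(cfg, rng)
            pairs = simulate_reads(genome, cfg, rng)
            write_fastq(pairs, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_fastq_roundtrip_restores_bookkeeping(self, tmp_path):
        cfg = small_cfg()
        rng = np.random.default_rng(6)
        genome = random_reference(cfg, rng)
        pairs = simulate_reads(genome, cfg, rng)
        write_fastq(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        back = read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert len(back) == len(pairs)
        assert back[0].frag_start == pairs[0].frag_start
        assert back[0].r1_seq == pairs[0].r1_seq


class TestAnalyticMap:
    def _dataset(self, tmp_path, **kw):
        cfg = small_cfg(base_error=0.0, mutation_rate=0.0, extend_matches=False, **kw)
        rng = np.random.default_rng(cfg.seed)
        ref = random_reference(cfg, rng)
        alt, truth = plant_indels(ref, cfg, rng)
        pairs = simulate_reads(alt, cfg, rng)
        sam = analytic_map(pairs, ref, truth, tmp_path / "out.sam", cfg)
        return cfg, ref, truth, pairs, sam

    def test_read_away_from_events_is_full_match(self, tmp_path):
        cfg, ref, truth, pairs, sam = self._dataset(tmp_path)
        full = [r for r in read_alignments(sam) if r.cigar == [("M", cfg.read_length)]]
        assert full  # the bulk of the data
        g = ref["sim"]
        for r in full[:100]:
            if not r.is_unmapped:
                assert r.seq == g[r.pos0 : r.pos0 + cfg.read_length]

    def test_clip_breakpoints_equal_truth_breakpoints(self, tmp_path):
        cfg, ref, truth, pairs, sam = self._dataset(tmp_path)
        bp_truth = set()
        for t in truth:
            bp_truth.add(t.pos1)  # 0-based event start
            if t.svtype == "DEL":
                bp_truth.add(t.pos1 + t.length)
        n_clipped = 0
        for r in read_alignments(sam):
            if r.is_unmapped:
                continue
            cg = r.cigar
            if cg[0][0] == "S":
                assert r.pos0 in bp_truth
                n_clipped += 1
            if cg[-1][0] == "S":
                assert r.reference_end0 in bp_truth
                n_clipped += 1
        assert n_clipped > 20

    def test_reads_inside_long_insertion_unmapped_with_mapped_mate(self, tmp_path):
        cfg, ref, truth, pairs, sam = self._dataset(
            tmp_path, n_del=0, n_ins=4, indel_sizes=(600,), coverage=60
        )
        um = [r for r in read_alignments(sam) if r.is_unmapped and not r.mate_is_unmapped]
        assert um
        ins_pos = {t.pos1 for t in truth}
        for r in um[:50]:
            assert any(abs(r.mate_pos0 - p) < 1500 for p in ins_pos)

    def test_sam_is_coordinate_sorted_and_paired(self, tmp_path):
        cfg, ref, truth, pairs, sam = self._dataset(tmp_path)
        positions = [r.pos0 for r in read_alignments(sam) if not r.is_unmapped]
        assert positions == sorted(positions)

    def test_specific_split_gives_expected_cigar(self, tmp_path):
        # one deletion; a fragment straddling its left breakpoint 90/60
        cfg = SimConfig(n_bins=1, n_del=1, n_ins=0, indel_sizes=(500,),
                        extend_matches=False, seed=9)
        rng = np.random.default_rng(cfg.seed)
        ref = random_reference(cfg, rng)
        alt, truth = plant_indels(ref, cfg, rng)
        t = truth[0]
        fs = t.pos1 - 90  # alt coords == ref coords left of the deletion
        pair = SimulatedPair(
            chrom="sim", frag_start=fs, frag_end=fs + 400, flip=0, hap=1, index=0,
            r1_seq=alt["sim"][fs : fs + 150],
            r2_seq=revcomp(alt["sim"][fs + 250 : fs + 400]),
        )
        sam = analytic_map([pair], ref, truth, tmp_path / "one.sam", cfg)
        read1 = next(r for r in read_alignments(sam) if not r.is_reverse)
        assert read1.cigar == [("M", 90), ("S", 60)]
        assert read1.reference_end0 == t.pos1


class TestSimulateDataset:
    def test_writes_all_artifacts(self, tmp_path):
        paths = simulate_dataset(small_cfg(), tmp_path / "d")
        for key in ("ref", "truth", "fq1", "fq2", "sam"):
            assert paths[key].exists()
        truth = read_truth_tsv(paths["truth"])
        assert len(truth) == 4
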