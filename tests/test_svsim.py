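import numpy as np
import pytest
from scipy import stats

from masv import (ReferenceGenome, SVRecord, SimConfig, apply_svs,
                  inject_flanking_noise, plan_svs, read_sv_vcf, revcomp,
                  simulate)
from masv.svsim import PlacementError

from conftest import random_genome

SMALL_BUCKETS = [(20, 100, 0.70), (101, 200, 0.20), (201, 400, 0.10)]


def reapply_truth(sequence: str, truth: list[SVRecord]) -> str:
    """Independent edit oracle: apply each SV right-to-left on a raw string."""
    out = sequence
    for sv in sorted(truth, key=lambda r: r.start, reverse=True):
        s, e = sv.start, sv.end
        if sv.svtype == "DEL":
            out = out[:s - 1] + out[e:]
        elif sv.svtype == "INS":
            out = out[:s] + sv.inserted_seq + out[s:]
        elif sv.svtype == "DUP":
            out = out[:e] + out[s - 1:e] + out[e:]
        elif sv.svtype == "INV":
            out = out[:s - 1] + revcomp(out[s - 1:e]) + out[e:]
    return out


class TestPlan:
    def test_requested_counts_and_length_range(self):
        cfg = SimConfig(n_per_type={"DEL": 100}, seed=11)
        truth = plan_svs(cfg, 4_600_000)
        assert len(truth) == 100
        assert all(r.svtype == "DEL" for r in truth)
        assert all(50 <= r.length <= 10_000 for r in truth)

    def test_zero_counts_give_empty_truth(self):
        assert plan_svs(SimConfig(seed=1), 4_600_000) == []

    def test_deterministic(self):
        cfg = SimConfig(n_per_type={"INS": 20, "INV": 5}, seed=3,
                        length_buckets=SMALL_BUCKETS)
        a = plan_svs(cfg, 100_000)
        b = plan_svs(cfg, 100_000)
        assert a == b

    def test_min_gap_respected(self):
        cfg = SimConfig(n_per_type={"DEL": 30}, seed=5,
                        length_buckets=SMALL_BUCKETS, flank_bp=50)
        truth = plan_svs(cfg, 100_000)
        for a, b in zip(truth, truth[1:]):
            assert b.start - a.end > cfg.min_gap_bp

    def test_bucket_occupancy_within_binomial_bounds(self):
        """500 SVs: bucket counts near (350, 100, 50) within 99% bounds."""
        cfg = SimConfig(n_per_type={"DEL": 500}, seed=42)
        truth = plan_svs(cfg, 4_641_652)
        edges = [(50, 1000), (1001, 5000), (5001, 10000)]
        weights = [0.70, 0.20, 0.10]
        counts = [sum(lo <= r.length <= hi for r in truth)
                  for lo, hi in edges]
        assert sum(counts) == 500
        for c, w in zip(counts, weights):
            lo = stats.binom.ppf(0.005, 500, w)
            hi = stats.binom.ppf(0.995, 500, w)
            assert lo <= c <= hi

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(n_per_type={"DEL": 50}, seed=1)
        with pytest.raises(PlacementError, match="achieved"):
            plan_svs(cfg, 5_000)

    def test_uniform_breakpoints(self):
        """Pooled start positions across seeds pass a chi-square
        uniformity test on 20 bins at alpha = 0.001."""
        glen = 1_000_000
        starts = []
        for seed in range(20):
            cfg = SimConfig(n_per_type={"INS": 100}, seed=seed,
                            length_buckets=SMALL_BUCKETS)
            starts.extend(r.start for r in plan_svs(cfg, glen))
        counts, _ = np.histogram(starts, bins=20, range=(1, glen))
        _, p = stats.chisquare(counts)
        assert p > 0.001


class TestApply:
    def test_deletion(self, tiny_genome):
        out = apply_svs(tiny_genome, [SVRecord("tiny", 3, "DEL", 4)])
        assert out.sequence == "ACGTAC"

    def test_tandem_duplication(self, tiny_genome):
        out = apply_svs(tiny_genome, [SVRecord("tiny", 3, "DUP", 4)])
        assert out.sequence == "ACGTACGTACGTAC"

    def test_inversion(self, tiny_genome):
        out = apply_svs(tiny_genome, [SVRecord("tiny", 2, "INV", 4)])
        assert out.sequence == "ATACGCGTAC"

    def test_insertion_anchor_left(self, tiny_genome):
        out = apply_svs(tiny_genome,
                        [SVRecord("tiny", 2, "INS", 3, inserted_seq="TTT")])
        assert out.sequence == "ACTTTGTACGTAC"

    def test_random_ins_content_recorded_back(self, tiny_genome):
        sv = SVRecord("tiny", 2, "INS", 5)
        out = apply_svs(tiny_genome, [sv], seed=9)
        assert sv.inserted_seq is not None and len(sv.inserted_seq) == 5
        assert out.sequence == "AC" + sv.inserted_seq + "GTACGTAC"

    def test_overlapping_truth_rejected_before_edit(self, small_genome):
        truth = [SVRecord(small_genome.contig_id, 100, "DEL", 50),
                 SVRecord(small_genome.contig_id, 120, "DEL", 50)]
        with pytest.raises(ValueError, match="overlap"):
            apply_svs(small_genome, truth)

    def test_length_bookkeeping(self, small_genome):
        cfg = SimConfig(n_per_type={"INS": 5, "DEL": 5, "DUP": 5, "INV": 5},
                        length_buckets=SMALL_BUCKETS, seed=17)
        truth = plan_svs(cfg, len(small_genome))
        for sv in truth:
            sv.contig = small_genome.contig_id
        out = apply_svs(small_genome, truth, seed=1)
        delta = (sum(r.length for r in truth if r.svtype in ("INS", "DUP"))
                 - sum(r.length for r in truth if r.svtype == "DEL"))
        assert len(out) == len(small_genome) + delta


class TestReconstruction:
    @pytest.mark.parametrize("seed", range(12))
    def test_truth_reapplication_reproduces_genome(self, small_genome, seed):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(
            n_per_type={t: int(rng.integers(0, 8))
                        for t in ("INS", "DEL", "DUP", "INV")},
            length_buckets=SMALL_BUCKETS, seed=seed)
        truth = plan_svs(cfg, len(small_genome))
        for sv in truth:
            sv.contig = small_genome.contig_id
        mutated = apply_svs(small_genome, truth, seed=seed + 1)
        assert reapply_truth(small_genome.sequence, truth) == mutated.sequence


class TestFlankNoise:
    def _genome_and_truth(self, n_sv=40, seed=0):
        g = random_genome(120_000, seed=99)
        cfg = SimConfig(n_per_type={"DEL": n_sv},
                        length_buckets=SMALL_BUCKETS, seed=seed)
        truth = plan_svs(cfg, len(g))
        for sv in truth:
            sv.contig = g.contig_id
        return g, apply_svs(g, truth), truth, cfg

    def test_zero_probabilities_leave_genome_unchanged(self):
        _, after, truth, cfg = self._genome_and_truth()
        cfg.p_flank_bps = cfg.p_flank_indel = 0.0
        noisy, small = inject_flanking_noise(after, truth, cfg, seed=4)
        assert noisy.sequence == after.sequence
        assert small == []

    def test_one_indel_per_flank_max_20bp(self):
        _, after, truth, cfg = self._genome_and_truth()
        cfg.p_flank_bps = 0.0
        cfg.p_flank_indel = 1.0
        _, small = inject_flanking_noise(after, truth, cfg, seed=4)
        # two flanks per SV; a handful can be lost to overlap reservations
        assert len(truth) * 2 * 0.9 <= len(small) <= len(truth) * 2
        for _pos, ref, alt in small:
            indel_len = abs(len(alt) - len(ref))
            assert 1 <= indel_len <= 20

    def test_substitution_count_within_poisson_bounds(self):
        """1,000 flanks at p = 0.01: substitutions within Poisson(10)
        99.9% bounds."""
        g = random_genome(600_000, seed=7)
        truth = [SVRecord(g.contig_id, 1 + 1200 * i + 500, "INS", 10,
                          inserted_seq="A" * 10)
                 for i in range(500)]
        after = apply_svs(g, truth)
        cfg = SimConfig(p_flank_bps=0.01, p_flank_indel=0.0, seed=0)
        _, small = inject_flanking_noise(after, truth, cfg, seed=123)
        n_sub = sum(1 for _p, r, a in small if len(r) == len(a) == 1)
        lo = stats.poisson.ppf(0.0005, 10.0)
        hi = stats.poisson.ppf(0.9995, 10.0)
        assert lo <= n_sub <= hi

    def test_variants_confined_to_flanks(self):
        g, after, truth, cfg = self._genome_and_truth()
        cfg.p_flank_bps = 1.0
        cfg.p_flank_indel = 0.5
        _, small = inject_flanking_noise(after, truth, cfg, seed=8)
        # map truth footprints to mutated coordinates (DELs only here)
        delta = 0
        flanks = []
        for sv in truth:
            pos = sv.start + delta
            flanks.append((pos - cfg.flank_bp, pos + cfg.flank_bp - 1))
            delta -= sv.length
        for pos, _r, _a in small:
            assert any(lo <= pos <= hi for lo, hi in flanks)


class TestSimulate:
    def test_zero_variant_genome_is_byte_identical(self, small_genome):
        result = simulate(small_genome, SimConfig(seed=5))
        assert result.mutated_genome.sequence == small_genome.sequence
        assert result.truth == [] and result.small_variants == []

    def test_same_seed_same_result(self, small_genome):
        cfg = SimConfig(n_per_type={"INS": 4, "DEL": 4},
                        length_buckets=SMALL_BUCKETS, seed=21,
                        p_flank_bps=0.5, p_flank_indel=0.5)
        r1 = simulate(small_genome, cfg)
        r2 = simulate(small_genome, cfg)
        assert r1.mutated_genome.sequence == r2.mutated_genome.sequence
        assert r1.truth == r2.truth
        assert r1.small_variants == r2.small_variants

    def test_outputs_round_trip(self, small_genome, tmp_path):
        cfg = SimConfig(n_per_type={"INS": 10},
                        length_buckets=SMALL_BUCKETS, seed=2)
        prefix = tmp_path / "sim"
        result = simulate(small_genome, cfg, out_prefix=prefix)
        back = read_sv_vcf(f"{prefix}.truth.vcf")
        assert len(back) == 10
        assert all(r.svtype == "INS" and r.inserted_seq for r in back)
        assert [r.start for r in back] == [r.start for r in result.truth]
        assert (tmp_path / "sim.fa").exists()
        assert (tmp_path / "sim.log").exists()
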