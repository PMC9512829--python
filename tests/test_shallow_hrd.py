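"""Segmentation vs exact DP oracles, LGA counting, and ensemble logic."""

import numpy as np
import pytest

from hrdkit import synth
from hrdkit.builds import GenomeBuild
from hrdkit.io_core import CoverageBins
from hrdkit.shallow_hrd import (
    SegmentationResult,
    ShallowConfig,
    calibrate_lga_cutoff,
    classify_lab2,
    consensus_from_labels,
    count_lga,
    log2_ratios,
    rebin,
    segment_bins,
    segment_signal,
)

from oracles import best_single_changepoint, dp_segment

MB = 1_000_000
CFG = ShallowConfig()


def make_bins(counts_by_chrom, width=5000, sample="S"):
    return CoverageBins(sample_id=sample, bin_width=width,
                        counts={c: np.asarray(v, float) for c, v in counts_by_chrom.items()})


class TestRebin:
    def test_identity_at_native_width(self):
        bins = make_bins({"A": [1, 2, 3, 4]})
        out = rebin(bins, 5)
        np.testing.assert_array_equal(out.counts["A"], [1, 2, 3, 4])

    def test_exact_sums(self):
        bins = make_bins({"A": [1, 2, 3, 4]})
        np.testing.assert_array_equal(rebin(bins, 10).counts["A"], [3, 7])

    def test_non_multiple_window_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rebin(make_bins({"A": [1, 2]}, width=4000), 10)

    def test_count_conservation_up_to_tail(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=1001).astype(float)
        bins = make_bins({"A": counts})
        out = rebin(bins, 50)  # factor 10; one trailing bin dropped
        assert out.counts["A"].sum() == counts[:1000].sum()


class TestSegmentation:
    def test_constant_signal_zero_changepoints(self):
        fit = segment_signal(np.full(200, 0.3))
        assert len(fit) == 1

    def test_single_step_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([np.zeros(100), np.full(100, 0.58)]) + rng.normal(0, 0.05, 200)
        fit = segment_signal(y)
        assert len(fit) == 2
        oracle_cp = best_single_changepoint(y)
        assert abs(fit[1][0] - oracle_cp) <= 2
        assert abs(fit[1][0] - 100) <= 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pelt_equals_unpruned_dp(self, seed):
        """PELT must reproduce the exact penalized optimum."""
        rng = np.random.default_rng(seed)
        y = np.concatenate([
            np.zeros(100), np.full(80, 0.58), np.full(120, -0.4)
        ]) + rng.normal(0, 0.08, 300)
        penalty = 0.5
        mine = [end for _, end, _ in segment_signal(y, penalty=penalty)]
        assert mine == dp_segment(y, penalty)

    def test_two_steps_recovered(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([
            np.zeros(100), np.full(100, 0.58), np.zeros(100)
        ]) + rng.normal(0, 0.05, 300)
        fit = segment_signal(y)
        assert len(fit) == 3
        assert abs(fit[1][0] - 100) <= 2 and abs(fit[2][0] - 200) <= 2

    def test_short_chromosome_skipped_with_warning(self):
        bins = make_bins({"A": np.full(400, 30.0), "B": np.full(5, 30.0)})
        with pytest.warns(UserWarning, match="too short"):
            res = segment_bins(bins, 5, CFG)
        assert res.skipped_chromosomes == ["B"]
        assert "A" in res.segments


TOY_BUILD = GenomeBuild(
    name="toy", lengths={"A": 100 * MB}, centromeres={"A": (48 * MB, 52 * MB)}
)


def seg_result(segments_mb, window_kb=50):
    segs = [(int(s * MB), int(e * MB), mu) for s, e, mu in segments_mb]
    return SegmentationResult(window_kb=window_kb, bin_width=window_kb * 1000,
                              segments={"A": segs})


class TestCountLga:
    def test_flat_genome(self):
        assert count_lga(seg_result([(0, 100, 0.0)]), TOY_BUILD, CFG) == 0

    def test_qualifying_junction(self):
        res = seg_result([(0, 12, 0.0), (12, 27, 0.58), (27, 48, 0.58)])
        assert count_lga(res, TOY_BUILD, CFG) == 1

    def test_small_gap_not_counted(self):
        res = seg_result([(0, 12, 0.0), (12, 27, 0.1)])
        assert count_lga(res, TOY_BUILD, CFG) == 0

    def test_sliver_smoothed_away(self):
        res = seg_result([(0, 12, 0.0), (12, 14, 1.0), (14, 29, 0.58)])
        assert count_lga(res, TOY_BUILD, CFG) == 1

    def test_junction_across_centromere_not_counted(self):
        res = seg_result([(0, 48, 0.0), (52, 100, 0.58)])
        assert count_lga(res, TOY_BUILD, CFG) == 0


class TestEnsemble:
    def test_unanimous_hrd(self):
        assert consensus_from_labels(["HRD"] * 6) == ("HRD", 1.0)

    def test_four_two_majority(self):
        consensus, agree = consensus_from_labels(["HRD"] * 4 + ["HRP"] * 2)
        assert consensus == "HRD"
        assert agree == pytest.approx(4 / 6)

    def test_tie_is_inconclusive(self):
        consensus, _ = consensus_from_labels(["HRD"] * 3 + ["HRP"] * 3)
        assert consensus == "Inconclusive"

    def test_flipping_one_label_moves_agreement_by_one_sixth(self):
        for n_hrd in range(6):
            labels = ["HRD"] * n_hrd + ["HRP"] * (6 - n_hrd)
            _, before = consensus_from_labels(labels)
            flipped = labels.copy()
            flipped[0] = "HRP" if flipped[0] == "HRD" else "HRD"
            _, after = consensus_from_labels(flipped)
            assert abs(after - before) == pytest.approx(1 / 6)

    def test_insufficient_coverage_failure(self, small_build):
        bins = make_bins({"c1": np.full(1000, 30.0)})  # far below 80% of genome
        call = classify_lab2(bins, small_build, CFG)
        assert call.consensus == "Inconclusive"
        assert call.failure_reason == "insufficient coverage"

    def test_determinism_and_scale_invariance(self, small_build):
        prof = synth.gen_profile((0, 0, 3), small_build, seed=21)
        bins = synth.gen_coverage(prof, small_build, window_kb=5, seed=22)
        call1 = classify_lab2(bins, small_build, CFG)
        call2 = classify_lab2(bins, small_build, CFG)
        assert [r.lga_count for r in call1.results] == [r.lga_count for r in call2.results]
        assert call1.consensus == call2.consensus
        scaled = CoverageBins(bins.sample_id, bins.bin_width,
                              {c: v * 8.0 for c, v in bins.counts.items()})
        call3 = classify_lab2(scaled, small_build, CFG)
        assert [r.lga_count for r in call3.results] == [r.lga_count for r in call1.results]
        for r1, r3 in zip(call1.results, call3.results):
            for chrom in r1.segments:
                assert [s[:2] for s in r1.segments[chrom]] == [s[:2] for s in r3.segments[chrom]]


class TestCutoffCalibration:
    def test_perfect_separation_takes_highest_tied_cutoff(self):
        rng = np.random.default_rng(0)
        hrp = rng.integers(0, 6, size=30).tolist()
        hrd = rng.integers(25, 40, size=30).tolist()
        assert calibrate_lga_cutoff(hrd, hrp) == 25

    def test_identical_distributions_warn(self):
        with pytest.warns(UserWarning, match="not separable"):
            calibrate_lga_cutoff([5] * 15, [5] * 15)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        hrd = rng.poisson(24, 30).tolist()
        hrp = rng.poisson(12, 30).tolist()
        got = calibrate_lga_cutoff(hrd, hrp)
        # literal scan over every integer threshold
        best_j, best_t = -np.inf, None
        for t in range(min(hrp + hrd), max(hrp + hrd) + 2):
            j = np.mean([x >= t for x in hrd]) + np.mean([x < t for x in hrp]) - 1
            if j > best_j or (j == best_j and t > best_t):
                best_j, best_t = j, t
        assert got == best_t

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            calibrate_lga_cutoff([20] * 5, [1] * 30)
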