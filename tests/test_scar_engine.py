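"""Scar components against brute-force per-base oracles and boundary rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdkit import synth
from hrdkit.builds import GenomeBuild, compact_build
from hrdkit.io_core import AlleleSpecificSegment, SegmentProfile
from hrdkit.scar_engine import (
    ScarConfig,
    ScarScores,
    calibrate_threshold,
    classify_lab1,
    compute_gi_score,
    compute_loh_score,
    compute_lst_score,
    compute_tai_score,
)

from oracles import scar_counts_per_base

MB = 1_000_000
CFG = ScarConfig()


def seg(chrom, start_mb, end_mb, total, minor):
    return AlleleSpecificSegment(
        chrom=chrom, start=int(start_mb * MB), end=int(end_mb * MB),
        total_cn=total, minor_cn=minor,
    )


def profile(*segments, sample="T"):
    return SegmentProfile(sample_id=sample, segments=list(segments))


@pytest.fixture(scope="module")
def toy_build():
    # one 100 Mb and one 70 Mb chromosome, metacentric-ish
    return GenomeBuild(
        name="toy",
        lengths={"A": 100 * MB, "B": 70 * MB},
        centromeres={"A": (48 * MB, 52 * MB), "B": (30 * MB, 34 * MB)},
    )


class TestLoh:
    def test_no_loh_segment_gives_zero(self, toy_build):
        prof = profile(seg("A", 0, 100, 2, 1))
        assert compute_loh_score(prof, toy_build, CFG) == 0

    def test_two_qualifying_runs_whole_chromosome_excluded(self, toy_build):
        prof = profile(
            seg("A", 0, 10, 2, 1),
            seg("A", 10, 30, 2, 0),   # 20 Mb LOH
            seg("A", 30, 40, 2, 1),
            seg("A", 40, 56, 1, 0),   # 16 Mb LOH
            seg("A", 56, 100, 2, 1),
            seg("B", 0, 70, 2, 0),    # whole-chromosome LOH: excluded
        )
        assert compute_loh_score(prof, toy_build, CFG) == 2
        assert scar_counts_per_base(prof, toy_build, CFG)[0] == 2

    def test_exactly_15mb_not_counted(self, toy_build):
        prof = profile(
            seg("A", 0, 10, 2, 1), seg("A", 10, 25, 2, 0), seg("A", 25, 100, 2, 1)
        )
        assert compute_loh_score(prof, toy_build, CFG) == 0
        assert scar_counts_per_base(prof, toy_build, CFG)[0] == 0


class TestTai:
    def test_balanced_diploid_gives_zero(self, toy_build):
        prof = profile(seg("A", 0, 100, 2, 1))
        assert compute_tai_score(prof, toy_build, CFG) == 0

    def test_telomeric_run_counts_centromere_crossing_does_not(self, toy_build):
        telomeric = profile(seg("A", 0, 20, 3, 1), seg("A", 20, 100, 2, 1))
        assert compute_tai_score(telomeric, toy_build, CFG) == 1
        crossing = profile(seg("A", 0, 53, 3, 1), seg("A", 53, 100, 2, 1))
        assert compute_tai_score(crossing, toy_build, CFG) == 0

    def test_both_telomeres_count_separately(self, toy_build):
        prof = profile(
            seg("A", 0, 15, 3, 1), seg("A", 15, 85, 2, 1), seg("A", 85, 100, 4, 1)
        )
        assert compute_tai_score(prof, toy_build, CFG) == 2
        assert scar_counts_per_base(prof, toy_build, CFG)[1] == 2

    def test_missing_centromere_is_an_error(self):
        build = GenomeBuild(name="nocen", lengths={"A": 100 * MB})
        prof = profile(seg("A", 0, 20, 3, 1))
        with pytest.raises(KeyError, match="centromere"):
            compute_tai_score(prof, build, CFG)


class TestLst:
    def test_single_state_genome_gives_zero(self, toy_build):
        prof = profile(seg("A", 0, 100, 2, 1), seg("B", 0, 70, 2, 1))
        assert compute_lst_score(prof, toy_build, CFG) == 0

    def test_junction_counts_and_sliver_is_smoothed(self, toy_build):
        plain = profile(seg("B", 0, 12, 2, 1), seg("B", 12, 27, 3, 1))
        assert compute_lst_score(plain, toy_build, CFG) == 1
        slivered = profile(
            seg("B", 0, 12, 2, 1), seg("B", 12, 14, 4, 2), seg("B", 14, 29, 3, 1)
        )
        assert compute_lst_score(slivered, toy_build, CFG) == 1

    def test_junction_straddling_centromere_not_counted(self, toy_build):
        prof = profile(seg("B", 20, 30, 2, 1), seg("B", 34, 46, 3, 1))
        assert compute_lst_score(prof, toy_build, CFG) == 0


class TestGiScore:
    def test_all_zero_components(self, toy_build):
        scores = compute_gi_score(profile(seg("A", 0, 100, 2, 1)), toy_build, CFG)
        assert (scores.loh_count, scores.tai_count, scores.lst_count) == (0, 0, 0)
        assert scores.gi_score == 0

    def test_targeted_profile_sums_to_43(self):
        build = compact_build(12, 200.0)
        prof = synth.gen_profile((12, 15, 16), build, seed=11)
        scores = compute_gi_score(prof, build, CFG)
        assert (scores.loh_count, scores.tai_count, scores.lst_count) == (12, 15, 16)
        assert scores.gi_score == 43

    def test_empty_profile_is_an_error(self, toy_build):
        with pytest.raises(ValueError, match="insufficient data"):
            compute_gi_score(profile(), toy_build, CFG)


class TestCalibration:
    def test_nearest_rank_fifth_percentile(self):
        assert calibrate_threshold(list(range(1, 101))) == 5

    def test_constant_scores(self):
        assert calibrate_threshold([42] * 30) == 42

    def test_n20_returns_minimum(self):
        scores = list(range(10, 30))
        assert calibrate_threshold(scores) == 10

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="20"):
            calibrate_threshold(list(range(19)))


class TestClassification:
    def test_score_above_threshold_is_hrd(self):
        call = classify_lab1(ScarScores(20, 10, 13), "wild_type")
        assert (call.label, call.rationale) == ("HRD", "score")

    def test_brca_override_rescues_low_score(self):
        call = classify_lab1(ScarScores(10, 10, 10), "mutated")
        assert (call.label, call.rationale) == ("HRD", "brca_override")

    def test_low_score_wild_type_is_hrp(self):
        assert classify_lab1(ScarScores(10, 10, 10), "wild_type").label == "HRP"

    def test_boundary_score_is_hrp_with_warning(self):
        with pytest.warns(UserWarning, match="threshold"):
            call = classify_lab1(ScarScores(14, 14, 14), "wild_type")
        assert call.label == "HRP"
        assert call.boundary_warning


class TestProperties:
    def test_oracle_equivalence_random_profiles(self, build):
        cfg = CFG
        chroms = ["1", "2", "3", "4"]
        for s in range(30):
            prof = synth.gen_random_profile(build, 50, seed=1000 + s, chroms=chroms)
            mine = compute_gi_score(prof, build, cfg)
            oracle = scar_counts_per_base(prof, build, cfg)
            assert (mine.loh_count, mine.tai_count, mine.lst_count) == oracle, f"seed {s}"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(target=st.tuples(*[st.integers(0, 6)] * 3), split_mb=st.integers(1, 50))
    def test_subdivision_invariance(self, target, split_mb):
        """Splitting any segment into equal-state halves never changes counts."""
        build = compact_build(4)
        prof = synth.gen_profile(target, build, seed=7)
        base = compute_gi_score(prof, build, CFG)
        split = []
        for s in prof.segments:
            mid = s.start + (split_mb * MB) % max(s.length, 1)
            if s.start < mid < s.end:
                split.append(AlleleSpecificSegment(s.chrom, s.start, mid, s.total_cn, s.minor_cn))
                split.append(AlleleSpecificSegment(s.chrom, mid, s.end, s.total_cn, s.minor_cn))
            else:
                split.append(s)
        after = compute_gi_score(SegmentProfile("split", split), build, CFG)
        assert (after.loh_count, after.tai_count, after.lst_count) == (
            base.loh_count, base.tai_count, base.lst_count,
        )

    def test_adding_disjoint_loh_run_adds_exactly_one(self, toy_build):
        base_segs = [
            seg("A", 0, 10, 2, 1), seg("A", 10, 30, 2, 0), seg("A", 30, 100, 2, 1)
        ]
        base = compute_gi_score(profile(*base_segs), toy_build, CFG)
        extra = profile(*base_segs, seg("B", 5, 25, 1, 0))
        after = compute_gi_score(extra, toy_build, CFG)
        assert after.loh_count == base.loh_count + 1
        assert after.tai_count == base.tai_count
        assert after.lst_count == base.lst_count
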