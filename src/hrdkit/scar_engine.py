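"""Genomic-scar scoring: LOH, TAI, LST counts and the genomic-instability call.

The genomic-instability (GI) score is the unweighted sum of three scar
components computed from an allele-specific copy-number segment profile:

* **LOH** — count of maximal runs of loss of heterozygosity (minor allele
  copy number 0, total copy number >= 1) longer than 15 Mb that do not span
  an entire chromosome.
* **TAI** — count of maximal allelic-imbalance runs (minor != major allele
  copy number) that touch a chromosome end, avoid the centromere, and are
  longer than 11 Mb.
* **LST** — count of junctions between adjacent copy-number states, per
  chromosome arm, where both flanking segments are >= 10 Mb after removing
  segments shorter than 3 Mb (small slivers are "smoothed away").

A sample is called HR-deficient when GI score > 42 (strictly), or when it
carries a deleterious BRCA1/2 variant regardless of score.  The threshold is
recalibratable as the nearest-rank fifth percentile of GI scores from a
reference set of BRCA-mutated samples.

All length thresholds live in :class:`ScarConfig` so published variants of
the scar definitions can be configured.  Sex chromosomes are excluded by
default (minor-allele semantics differ there); profiles arrive already
adjusted for purity and ploidy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .builds import GenomeBuild
from .io_core import AlleleSpecificSegment, SegmentProfile

__all__ = [
    "ScarConfig",
    "ScarScores",
    "GiCall",
    "compute_loh_score",
    "compute_tai_score",
    "compute_lst_score",
    "compute_gi_score",
    "calibrate_threshold",
    "classify_lab1",
]


@dataclass(frozen=True)
class ScarConfig:
    """Length thresholds (bp) and the HRD decision threshold."""

    loh_min_len: int = 15_000_000
    tai_min_len: int = 11_000_000
    lst_min_seg: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    gap_merge_max: int = 1_000_000  # assembly gaps below this merge runs
    gi_threshold: int = 42
    threshold_percentile: float = 5.0
    include_sex_chromosomes: bool = False

    def __post_init__(self) -> None:
        for name in ("loh_min_len", "tai_min_len", "lst_min_seg", "lst_smooth_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")


@dataclass(frozen=True)
class ScarScores:
    loh_count: int
    tai_count: int
    lst_count: int

    def __post_init__(self) -> None:
        if min(self.loh_count, self.tai_count, self.lst_count) < 0:
            raise ValueError("scar components must be non-negative")

    @property
    def gi_score(self) -> int:
        return self.loh_count + self.tai_count + self.lst_count


@dataclass(frozen=True)
class GiCall:
    sample_id: str
    scores: ScarScores
    brca_status: str  # mutated | wild_type | unknown
    label: str  # HRD | HRP
    rationale: str  # score | brca_override
    boundary_warning: bool = False


_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _prepared_segments(
    profile: SegmentProfile, build: GenomeBuild, cfg: ScarConfig
) -> dict[str, list[tuple[int, int, int, int]]]:
    """Validated, integerized (start, end, total, minor) per chromosome.

    Allele copy numbers are rounded half-away-from-zero and the minor allele
    is re-oriented so that minor <= major.
    """
    prof = profile.validate(build)
    per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for seg in prof.segments:
        chrom = build.normalize_chrom(seg.chrom)
        if not cfg.include_sex_chromosomes and chrom in _SEX_CHROMS:
            continue
        total = _round_half_away(seg.total_cn)
        minor = _round_half_away(seg.minor_cn)
        minor = min(minor, total - minor)
        per_chrom.setdefault(chrom, []).append((seg.start, seg.end, total, minor))
    return per_chrom


def _merged_runs(
    segs: list[tuple[int, int, int, int]], predicate, gap_max: int
) -> list[tuple[int, int, int]]:
    """Maximal runs of predicate-true segments: (span_start, span_end, covered_len).

    Consecutive qualifying segments separated by a gap <= gap_max belong to
    the same run; the run length is the covered (not spanned) length.
    """
    runs: list[tuple[int, int, int]] = []
    cur: list[tuple[int, int]] | None = None
    for start, end, total, minor in segs:
        if predicate(total, minor):
            if cur is not None and start - cur[-1][1] <= gap_max:
                cur.append((start, end))
            else:
                if cur is not None:
                    runs.append(_close_run(cur))
                cur = [(start, end)]
        else:
            if cur is not None:
                runs.append(_close_run(cur))
                cur = None
    if cur is not None:
        runs.append(_close_run(cur))
    return runs


def _close_run(pieces: list[tuple[int, int]]) -> tuple[int, int, int]:
    covered = sum(e - s for s, e in pieces)
    return (pieces[0][0], pieces[-1][1], covered)


def compute_loh_score(
    profile: SegmentProfile, build: GenomeBuild, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count LOH runs longer than ``loh_min_len`` not spanning a whole chromosome."""
    count = 0
    for chrom, segs in _prepared_segments(profile, build, cfg).items():
        chrom_len = build.lengths[chrom]
        for span_start, span_end, covered in _merged_runs(
            segs, lambda t, m: m == 0 and t >= 1, cfg.gap_merge_max
        ):
            if covered > cfg.loh_min_len and not (span_start == 0 and span_end == chrom_len):
                count += 1
    return count


def compute_tai_score(
    profile: SegmentProfile, build: GenomeBuild, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count telomeric allelic-imbalance runs.

    A run qualifies when it touches a chromosome end, does not intersect the
    centromere interval, and its covered length exceeds ``tai_min_len``.
    """
    count = 0
    for chrom, segs in _prepared_segments(profile, build, cfg).items():
        chrom_len = build.lengths[chrom]
        cen_start, cen_end = build.centromere(chrom)
        for span_start, span_end, covered in _merged_runs(
            segs, lambda t, m: m != t - m, cfg.gap_merge_max
        ):
            touches_end = span_start == 0 or span_end == chrom_len
            crosses_cen = span_start < cen_end and span_end > cen_start
            if touches_end and not crosses_cen and covered > cfg.tai_min_len:
                count += 1
    return count


def _split_at_centromere(
    segs: list[tuple[int, int, int, int]], cen: tuple[int, int]
) -> tuple[list, list]:
    """Clip segments to the p and q arms, discarding centromeric parts."""
    cs, ce = cen
    p, q = [], []
    for start, end, total, minor in segs:
        if start < cs:
            p.append((start, min(end, cs), total, minor))
        if end > ce:
            q.append((max(start, ce), end, total, minor))
    return p, q


def _merge_equal_states(
    segs: list[tuple[int, int, int, int]], gap_max: int
) -> list[tuple[int, int, int, int, int]]:
    """Merge adjacent segments with identical (total, minor) state.

    Returns (span_start, span_end, covered_len, total, minor) tuples; only
    gaps <= gap_max are bridged.
    """
    out: list[list] = []
    for start, end, total, minor in segs:
        if out and out[-1][3] == total and out[-1][4] == minor and start - out[-1][1] <= gap_max:
            out[-1][1] = end
            out[-1][2] += end - start
        else:
            out.append([start, end, end - start, total, minor])
    return [tuple(o) for o in out]


def compute_lst_score(
    profile: SegmentProfile, build: GenomeBuild, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count large-scale state transitions, evaluated per chromosome arm.

    Per arm: merge equal states, drop segments shorter than
    ``lst_smooth_len``, re-merge equal states across the resulting gaps
    (bridging at most ``lst_smooth_len``), then count junctions where both
    flanking segments are >= ``lst_min_seg``, the copy state changes, and
    the gap between them is <= ``lst_smooth_len``.
    """
    count = 0
    for chrom, segs in _prepared_segments(profile, build, cfg).items():
        for arm_segs in _split_at_centromere(segs, build.centromere(chrom)):
            merged = _merge_equal_states(arm_segs, cfg.gap_merge_max)
            kept = [m for m in merged if m[2] >= cfg.lst_smooth_len]
            # re-merge equal states now adjacent across smoothed-away slivers
            smoothed: list[list] = []
            for span_start, span_end, covered, total, minor in kept:
                if (
                    smoothed
                    and smoothed[-1][3] == total
                    and smoothed[-1][4] == minor
                    and span_start - smoothed[-1][1] <= cfg.lst_smooth_len
                ):
                    smoothed[-1][1] = span_end
                    smoothed[-1][2] += covered
                else:
                    smoothed.append([span_start, span_end, covered, total, minor])
            for left, right in zip(smoothed, smoothed[1:]):
                gap = right[0] - left[1]
                states_differ = (left[3], left[4]) != (right[3], right[4])
                if (
                    gap <= cfg.lst_smooth_len
                    and states_differ
                    and left[2] >= cfg.lst_min_seg
                    and right[2] >= cfg.lst_min_seg
                ):
                    count += 1
    return count


def compute_gi_score(
    profile: SegmentProfile, build: GenomeBuild, cfg: ScarConfig = ScarConfig()
) -> ScarScores:
    """All three scar components; raises on an empty profile."""
    if not profile.segments:
        raise ValueError(f"sample {profile.sample_id}: insufficient data (no segments)")
    return ScarScores(
        loh_count=compute_loh_score(profile, build, cfg),
        tai_count=compute_tai_score(profile, build, cfg),
        lst_count=compute_lst_score(profile, build, cfg),
    )


def calibrate_threshold(
    reference_scores: list[int], percentile: float = 5.0
) -> int:
    """Nearest-rank percentile of GI scores from a BRCA-mutated reference set.

    With n scores the nearest-rank p-th percentile is the ceil(p/100 * n)-th
    order statistic.  At least 20 scores are required; below that the tail
    percentile is too unstable to define a decision threshold.
    """
    n = len(reference_scores)
    if n < 20:
        raise ValueError(f"need >= 20 reference scores, got {n}")
    rank = math.ceil(percentile / 100.0 * n)
    return sorted(reference_scores)[rank - 1]


def classify_lab1(
    scores: ScarScores,
    brca_status: str = "unknown",
    cfg: ScarConfig = ScarConfig(),
    sample_id: str = "",
) -> GiCall:
    """HRD/HRP call: GI score strictly above threshold, or BRCA override.

    A score exactly at the threshold is called HRP (the rule requires
    strictly greater) and flagged with a boundary warning.
    """
    if brca_status not in {"mutated", "wild_type", "unknown"}:
        raise ValueError(f"unknown BRCA status {brca_status!r}")
    boundary = scores.gi_score == cfg.gi_threshold
    if boundary:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'}: GI score exactly at threshold "
            f"{cfg.gi_threshold}; called HRP under the strict-inequality rule",
            stacklevel=2,
        )
    if scores.gi_score > cfg.gi_threshold:
        label, rationale = "HRD", "score"
    elif brca_status == "mutated":
        label, rationale = "HRD", "brca_override"
    else:
        label, rationale = "HRP", "score"
    return GiCall(
        sample_id=sample_id,
        scores=scores,
        brca_status=brca_status,
        label=label,
        rationale=rationale,
        boundary_warning=boundary,
    )
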