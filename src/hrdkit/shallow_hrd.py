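"""Shallow-WGS HRD scoring by cross-window segmentation agreement.

Low-coverage (~0.4-0.8x) whole-genome read counts are binned, re-binned at
six window sizes spanning 5-1000 kb, segmented into piecewise-constant
log2-ratio profiles, and scored by counting large-scale genomic alterations
(LGAs): junctions between adjacent >= 10 Mb segments whose mean log2 ratios
differ by at least 0.2, per chromosome arm, after smoothing away segments
shorter than 3 Mb.  Each window size yields one model; a model labels the
sample HRD when its LGA count reaches the cutoff (default 20).  The ensemble
call is the majority label when at least 4 of 6 models agree, otherwise
Inconclusive.  BRCA status is never consulted.

Segmentation is exact penalized least squares solved with PELT (pruned
dynamic programming), deterministic for fixed input.  The per-changepoint
penalty defaults to 3 * sigma^2 * log(n) with sigma estimated robustly from
first differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .builds import GenomeBuild
from .io_core import CoverageBins

__all__ = [
    "ShallowConfig",
    "SegmentationResult",
    "EnsembleCall",
    "rebin",
    "log2_ratios",
    "segment_bins",
    "count_lga",
    "classify_lab2",
    "consensus_from_labels",
    "calibrate_lga_cutoff",
]


@dataclass(frozen=True)
class ShallowConfig:
    window_sizes_kb: tuple[int, ...] = (5, 10, 50, 100, 500, 1000)
    lga_min_seg: int = 10_000_000
    lga_smooth_len: int = 3_000_000
    lga_min_cn_gap: float = 0.2  # log2-ratio difference
    lga_hrd_cutoff: int = 20
    min_agreement: int = 4  # of six models
    penalty: float | None = None  # per-changepoint cost; None = auto
    min_bins_per_chrom: int = 10
    min_genome_fraction: float = 0.8

    def __post_init__(self) -> None:
        w = self.window_sizes_kb
        if len(w) != 6 or list(w) != sorted(w) or w[0] < 5 or w[-1] > 1000:
            raise ValueError("need exactly six ascending window sizes within [5, 1000] kb")


@dataclass
class SegmentationResult:
    """Piecewise-constant fit at one window size.

    ``segments`` maps chromosome -> list of (start_bp, end_bp, mean_log2).
    """

    window_kb: int
    bin_width: int
    segments: dict[str, list[tuple[int, int, float]]]
    skipped_chromosomes: list[str] = field(default_factory=list)
    lga_count: int | None = None

    def changepoints(self, chrom: str) -> list[int]:
        return [seg[0] for seg in self.segments[chrom][1:]]


@dataclass
class EnsembleCall:
    sample_id: str
    results: list[SegmentationResult]
    model_labels: list[str]
    agreement: float
    consensus: str  # HRD | HRP | Inconclusive
    failure_reason: str | None = None


def rebin(bins: CoverageBins, window_kb: int) -> CoverageBins:
    """Aggregate counts into a coarser window; trailing partial windows drop.

    The target window must be an integer multiple of the source bin width.
    """
    window_bp = window_kb * 1000
    if window_bp % bins.bin_width != 0:
        raise ValueError(
            f"window {window_kb} kb is not a multiple of the bin width "
            f"{bins.bin_width} bp"
        )
    factor = window_bp // bins.bin_width
    if factor == 1:
        return CoverageBins(bins.sample_id, bins.bin_width, dict(bins.counts))
    out: dict[str, np.ndarray] = {}
    for chrom, arr in bins.counts.items():
        n = (len(arr) // factor) * factor
        out[chrom] = arr[:n].reshape(-1, factor).sum(axis=1)
    return CoverageBins(sample_id=bins.sample_id, bin_width=window_bp, counts=out)


def log2_ratios(bins: CoverageBins) -> dict[str, np.ndarray]:
    """Median-centred log2 ratios; zero counts are floored at 0.5 reads."""
    allc = np.concatenate([v for v in bins.counts.values()]) if bins.counts else np.array([])
    if allc.size == 0:
        raise ValueError(f"sample {bins.sample_id}: no bins")
    med = np.median(allc)
    if med <= 0:
        raise ValueError(f"sample {bins.sample_id}: non-positive median count")
    return {c: np.log2(np.maximum(v, 0.5) / med) for c, v in bins.counts.items()}


# ---------------------------------------------------------------------------
# PELT segmentation
# ---------------------------------------------------------------------------

_PELT_JIT = None


def _get_pelt():
    global _PELT_JIT
    if _PELT_JIT is None:
        from numba import njit

        _PELT_JIT = njit(cache=False)(_pelt_py)
    return _PELT_JIT


def _pelt_py(cum, cum2, beta):  # pragma: no cover - exercised via jit
    n = cum.shape[0] - 1
    F = np.empty(n + 1)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    cand = np.empty(n + 1, dtype=np.int64)
    vals = np.empty(n + 1)
    cand[0] = 0
    m = 1
    for t in range(1, n + 1):
        ct = cum[t]
        c2t = cum2[t]
        best = np.inf
        arg = 0
        for i in range(m):
            s = cand[i]
            d = ct - cum[s]
            v = F[s] + (c2t - cum2[s]) - d * d / (t - s)
            vals[i] = v
            if v < best:
                best = v
                arg = s
        F[t] = best + beta
        prev[t] = arg
        k = 0
        for i in range(m):
            if vals[i] <= best + beta:
                cand[k] = cand[i]
                k += 1
        cand[k] = t
        m = k + 1
    # backtrack
    cps = np.empty(n + 1, dtype=np.int64)
    j = 0
    t = n
    while t > 0:
        cps[j] = t
        j += 1
        t = prev[t]
    return cps[:j][::-1].copy()


def _auto_penalty(y: np.ndarray) -> float:
    if len(y) < 3:
        return 1.0
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0)
    return max(3.0 * sigma * sigma * np.log(len(y)), 1e-6)


def segment_signal(y: np.ndarray, penalty: float | None = None) -> list[tuple[int, int, float]]:
    """Penalized least-squares changepoint fit of one signal.

    Returns (start_bin, end_bin, mean) triples covering [0, len(y)).
    """
    y = np.asarray(y, dtype=float)
    beta = _auto_penalty(y) if penalty is None else float(penalty)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    ends = _get_pelt()(cum, cum2, beta)
    out = []
    start = 0
    for end in ends:
        out.append((start, int(end), float((cum[end] - cum[start]) / (end - start))))
        start = int(end)
    return out


def segment_bins(
    bins: CoverageBins, window_kb: int, cfg: ShallowConfig = ShallowConfig()
) -> SegmentationResult:
    """Rebin to ``window_kb`` and segment each chromosome's log2 ratios.

    Chromosomes with fewer than ``min_bins_per_chrom`` bins after rebinning
    are skipped with a warning and recorded in the result.
    """
    rb = rebin(bins, window_kb)
    ratios = log2_ratios(rb)
    segments: dict[str, list[tuple[int, int, float]]] = {}
    skipped: list[str] = []
    for chrom, y in ratios.items():
        if len(y) < cfg.min_bins_per_chrom:
            skipped.append(chrom)
            warnings.warn(
                f"sample {bins.sample_id}: chromosome {chrom} too short after "
                f"rebinning to {window_kb} kb ({len(y)} bins); skipped",
                stacklevel=2,
            )
            continue
        fit = segment_signal(y, cfg.penalty)
        segments[chrom] = [
            (s * rb.bin_width, e * rb.bin_width, mu) for s, e, mu in fit
        ]
    return SegmentationResult(
        window_kb=window_kb, bin_width=rb.bin_width, segments=segments,
        skipped_chromosomes=skipped,
    )


# ---------------------------------------------------------------------------
# LGA counting
# ---------------------------------------------------------------------------

def _arm_pieces(
    segs: list[tuple[int, int, float]], cen: tuple[int, int]
) -> tuple[list, list]:
    cs, ce = cen
    p, q = [], []
    for start, end, mu in segs:
        if start < cs:
            p.append((start, min(end, cs), mu))
        if end > ce:
            q.append((max(start, ce), end, mu))
    return p, q


def count_lga(
    seg: SegmentationResult, build: GenomeBuild, cfg: ShallowConfig = ShallowConfig()
) -> int:
    """Count large-scale genomic alterations in a segmented profile.

    Per arm: drop segments shorter than ``lga_smooth_len``, merge neighbours
    whose means differ by less than ``lga_min_cn_gap`` (length-weighted),
    then count junctions with both flanks >= ``lga_min_seg`` and
    |delta log2| >= ``lga_min_cn_gap``.
    """
    total = 0
    for chrom, segs in seg.segments.items():
        cen = build.centromere(build.normalize_chrom(chrom))
        for arm in _arm_pieces(segs, cen):
            kept = [(s, e, e - s, mu) for s, e, mu in arm if e - s >= cfg.lga_smooth_len]
            merged: list[list] = []
            for s, e, ln, mu in kept:
                if (
                    merged
                    and abs(merged[-1][3] - mu) < cfg.lga_min_cn_gap
                    and s - merged[-1][1] <= cfg.lga_smooth_len
                ):
                    prev = merged[-1]
                    w = prev[2] + ln
                    prev[3] = (prev[3] * prev[2] + mu * ln) / w
                    prev[1], prev[2] = e, w
                else:
                    merged.append([s, e, ln, mu])
            for left, right in zip(merged, merged[1:]):
                gap = right[0] - left[1]
                if (
                    gap <= cfg.lga_smooth_len
                    and left[2] >= cfg.lga_min_seg
                    and right[2] >= cfg.lga_min_seg
                    and abs(right[3] - left[3]) >= cfg.lga_min_cn_gap
                ):
                    total += 1
    return total


def classify_lab2(
    bins: CoverageBins, build: GenomeBuild, cfg: ShallowConfig = ShallowConfig()
) -> EnsembleCall:
    """Six-window ensemble HRD call by cross-model agreement.

    Each window-size model labels the sample HRD when its LGA count is
    >= ``lga_hrd_cutoff``; the consensus is the majority label if at least
    ``min_agreement`` models agree, otherwise Inconclusive.  BRCA status is
    never an input.
    """
    covered = bins.total_span()
    if covered < cfg.min_genome_fraction * build.total_length():
        return EnsembleCall(
            sample_id=bins.sample_id, results=[], model_labels=[],
            agreement=0.0, consensus="Inconclusive",
            failure_reason="insufficient coverage",
        )
    results: list[SegmentationResult] = []
    labels: list[str] = []
    for w in cfg.window_sizes_kb:
        res = segment_bins(bins, w, cfg)
        res = replace(res, lga_count=count_lga(res, build, cfg))
        results.append(res)
        labels.append("HRD" if res.lga_count >= cfg.lga_hrd_cutoff else "HRP")
    consensus, agreement = consensus_from_labels(labels, cfg.min_agreement)
    return EnsembleCall(
        sample_id=bins.sample_id, results=results, model_labels=labels,
        agreement=agreement, consensus=consensus,
    )


def consensus_from_labels(
    labels: list[str], min_agreement: int = 4
) -> tuple[str, float]:
    """Majority consensus and agreement fraction over per-model labels.

    Returns Inconclusive when fewer than ``min_agreement`` models share the
    majority label (an exact tie is Inconclusive by construction).
    """
    n_hrd = labels.count("HRD")
    n_hrp = len(labels) - n_hrd
    majority = "HRD" if n_hrd >= n_hrp else "HRP"
    agree = max(n_hrd, n_hrp)
    consensus = majority if agree >= min_agreement else "Inconclusive"
    return consensus, agree / len(labels)


def calibrate_lga_cutoff(
    hrd_counts: list[int], hrp_counts: list[int], min_group: int = 10
) -> int:
    """Integer LGA cutoff maximizing Youden's J on a labeled training set.

    Predicting HRD when count >= cutoff, J(t) = sensitivity + specificity - 1
    is scanned over all integer thresholds; ties break toward the higher
    cutoff (higher specificity).
    """
    if len(hrd_counts) < min_group or len(hrp_counts) < min_group:
        raise ValueError(f"need >= {min_group} samples per group")
    hrd = np.asarray(hrd_counts, dtype=float)
    hrp = np.asarray(hrp_counts, dtype=float)
    lo = int(min(hrd.min(), hrp.min()))
    hi = int(max(hrd.max(), hrp.max())) + 1
    best_t, best_j = lo, -np.inf
    for t in range(lo, hi + 1):
        j = (hrd >= t).mean() + (hrp < t).mean() - 1.0
        if j >= best_j:  # >= breaks ties toward the larger threshold
            best_j, best_t = j, t
    if best_j <= 0:
        warnings.warn(
            "training groups are not separable (Youden's J <= 0); the "
            "calibrated cutoff is uninformative",
            stacklevel=2,
        )
    return best_t
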