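"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are pure functions of their parameters and a seed:

* :func:`gen_profile` builds an allele-specific segment profile whose scar
  counts (LOH, TAI, LST) equal a requested target triple exactly, by
  construction.  Scar features are insulated from each other: LOH and TAI
  runs are laid down as alternating sub-3 Mb slivers (so they are invisible
  to LST smoothing), and LST junction pairs are flanked by 3.6-5 Mb buffer
  segments (long enough to survive smoothing, short enough never to qualify
  as LST flanks).
* :func:`gen_coverage` draws negative-binomial (gamma-Poisson) read counts
  over a profile at shallow depth (0.4-0.8x), with log-scale extra-
  dispersion sigma; sigma = 0 degenerates to Poisson counting noise.
* :func:`gen_cells` simulates per-cell RAD51/geminin/gamma-H2AX records.
* :func:`gen_cohort` simulates a trial-like cohort: a latent HRD state per
  sample, per-assay calls with designed sensitivity/specificity and
  missingness, exponential progression times with a designed hazard ratio,
  and RECIST-style response categories.
* :func:`fixture_table2` returns the published cross-tabulations of the
  three index assays against the reference assay, used as frozen fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builds import GenomeBuild
from .concordance_stats import AssayCall, ContingencyTable2x2
from .io_core import AlleleSpecificSegment, CellRecord, CoverageBins, SegmentProfile, SlideSample

__all__ = [
    "SynthSpec",
    "AssayModel",
    "gen_profile",
    "gen_random_profile",
    "gen_coverage",
    "gen_cells",
    "gen_cohort",
    "fixture_table2",
    "table2_margins",
    "fixture_table2_calls",
]

_GRID = 100_000  # all synthetic breakpoints sit on a 0.1 Mb grid
_MB = 1_000_000

_FILLER = (2, 1)  # balanced diploid
_SEP = 36  # separator filler between features, grid units (3.6 Mb)


def _g(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer in [lo, hi], in grid units."""
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# scar-target profiles
# ---------------------------------------------------------------------------

def _slivers(rng: np.random.Generator, total: int, states: tuple[tuple[int, int], ...]):
    """Split ``total`` grid units into alternating-state pieces, each < 3 Mb."""
    pieces: list[tuple[int, tuple[int, int]]] = []
    remaining = total
    i = 0
    while remaining > 50:  # > 5.0 Mb
        ln = _g(rng, 20, 29)
        pieces.append((ln, states[i % 2]))
        remaining -= ln
        i += 1
    if remaining > 29:  # split the tail into two sub-3 Mb pieces
        half = remaining // 2
        pieces.append((half, states[i % 2]))
        pieces.append((remaining - half, states[(i + 1) % 2]))
    elif remaining > 0:
        pieces.append((remaining, states[i % 2]))
    return pieces


def _make_feature(kind: str, rng: np.random.Generator) -> list[tuple[int, tuple[int, int]]]:
    """A feature as (length_grid_units, (total_cn, minor_cn)) pieces."""
    if kind == "loh":
        # interior LOH run > 15 Mb; alternating totals keep it out of LST
        return _slivers(rng, _g(rng, 162, 299), ((2, 0), (1, 0)))
    if kind == "tai":
        # telomeric allelic imbalance > 11 Mb, minor != major, minor != 0
        return _slivers(rng, _g(rng, 124, 249), ((3, 1), (4, 1)))
    if kind == "lst":
        # one junction between two >= 10 Mb states, buffered on both sides
        return [
            (_g(rng, 36, 42), (8, 4)),
            (_g(rng, 105, 125), (4, 2)),
            (_g(rng, 105, 125), (6, 3)),
            (_g(rng, 36, 42), (8, 4)),
        ]
    raise ValueError(kind)


def _feature_len(feature) -> int:
    return sum(ln for ln, _ in feature)


@dataclass
class _Arm:
    chrom: str
    side: str  # p | q
    start: int  # grid units
    end: int
    tai: list | None = None
    features: list = field(default_factory=list)
    used: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def free(self) -> int:
        tai_len = _feature_len(self.tai) if self.tai else 0
        return self.length - tai_len - self.used - _SEP  # final separator


def gen_profile(
    targets: tuple[int, int, int],
    build: GenomeBuild,
    seed: int,
    sample_id: str = "synthetic",
) -> SegmentProfile:
    """Profile whose scar counts equal ``targets`` = (LOH, TAI, LST) exactly.

    Raises ValueError when the targets do not fit on the build.
    """
    n_loh, n_tai, n_lst = targets
    if min(targets) < 0:
        raise ValueError("targets must be non-negative")
    rng = np.random.default_rng(seed)

    arms: list[_Arm] = []
    for chrom in build.chromosomes:
        cs, ce = build.centromere(chrom)
        length = build.lengths[chrom]
        if cs % _GRID or ce % _GRID or length % _GRID:
            raise ValueError(
                f"build {build.name!r}: chromosome {chrom} coordinates are "
                f"not aligned to the {_GRID} bp synthesis grid"
            )
        arms.append(_Arm(chrom, "p", 0, cs // _GRID))
        arms.append(_Arm(chrom, "q", ce // _GRID, length // _GRID))

    # telomeric features first: one per arm, largest arms preferred
    tai_feats = [_make_feature("tai", rng) for _ in range(n_tai)]
    for feat in sorted(tai_feats, key=_feature_len, reverse=True):
        candidates = [a for a in arms if a.tai is None and a.free >= _feature_len(feat)]
        if not candidates:
            raise ValueError(f"targets {targets} infeasible on build {build.name!r} (TAI)")
        max(candidates, key=lambda a: a.free).tai = feat

    interior = [_make_feature("loh", rng) for _ in range(n_loh)]
    interior += [_make_feature("lst", rng) for _ in range(n_lst)]
    for feat in sorted(interior, key=_feature_len, reverse=True):
        need = _SEP + _feature_len(feat)
        candidates = [a for a in arms if a.free >= need]
        if not candidates:
            raise ValueError(f"targets {targets} infeasible on build {build.name!r}")
        arm = max(candidates, key=lambda a: a.free)
        arm.features.append(feat)
        arm.used += need

    # emit segments; q arms are assembled from the telomere inward
    segments: list[AlleleSpecificSegment] = []

    def emit(chrom: str, start_g: int, pieces: list[tuple[int, tuple[int, int]]]):
        cursor = start_g
        for ln, (total, minor) in pieces:
            segments.append(
                AlleleSpecificSegment(
                    chrom=chrom, start=cursor * _GRID, end=(cursor + ln) * _GRID,
                    total_cn=total, minor_cn=minor,
                )
            )
            cursor += ln

    for arm in arms:
        pieces: list[tuple[int, tuple[int, int]]] = []
        if arm.tai:
            pieces.extend(arm.tai)
        for feat in arm.features:
            pieces.append((_SEP, _FILLER))
            pieces.extend(feat)
        filled = sum(ln for ln, _ in pieces)
        tail = arm.length - filled
        if tail > 0:
            pieces.append((tail, _FILLER))
        if arm.side == "q":  # mirror: telomere is the right end
            pieces = list(reversed(pieces))
        emit(arm.chrom, arm.start, pieces)

    # cover centromeres with balanced filler so profiles are contiguous
    for chrom in build.chromosomes:
        cs, ce = build.centromere(chrom)
        segments.append(
            AlleleSpecificSegment(chrom=chrom, start=cs, end=ce, total_cn=2, minor_cn=1)
        )

    return SegmentProfile(sample_id=sample_id, segments=segments).validate(build)


_RANDOM_STATES = [
    (2, 1), (2, 1), (2, 1),  # balanced diploid, weighted up
    (2, 0), (1, 0), (3, 0),  # LOH states
    (3, 1), (4, 1), (5, 2),  # imbalanced
    (4, 2), (6, 3), (2, 2), (1, 1), (3, 1),
]


def gen_random_profile(
    build: GenomeBuild,
    n_segments: int,
    seed: int,
    chroms: list[str] | None = None,
    sample_id: str = "random",
) -> SegmentProfile:
    """Fully covering random profile with grid-aligned breakpoints.

    Used for oracle-equivalence studies: segment boundaries land on the
    0.1 Mb grid so a per-base oracle at that resolution is exact.
    """
    rng = np.random.default_rng(seed)
    chroms = chroms or build.chromosomes
    n_segments = max(n_segments, len(chroms))
    # split the segment budget across chromosomes
    per_chrom = np.full(len(chroms), n_segments // len(chroms))
    per_chrom[: n_segments % len(chroms)] += 1
    segments: list[AlleleSpecificSegment] = []
    for chrom, k in zip(chroms, per_chrom):
        n_units = build.lengths[chrom] // _GRID
        k = int(min(k, n_units))
        cuts = np.sort(rng.choice(np.arange(1, n_units), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [n_units]])
        for lo, hi in zip(bounds, bounds[1:]):
            total, minor = _RANDOM_STATES[rng.integers(len(_RANDOM_STATES))]
            segments.append(
                AlleleSpecificSegment(
                    chrom=chrom, start=int(lo) * _GRID, end=int(hi) * _GRID,
                    total_cn=total, minor_cn=minor,
                )
            )
    return SegmentProfile(sample_id=sample_id, segments=segments).validate(build)


# ---------------------------------------------------------------------------
# shallow-WGS coverage
# ---------------------------------------------------------------------------

def gen_coverage(
    profile: SegmentProfile,
    build: GenomeBuild,
    window_kb: int = 5,
    depth_factor: float = 0.6,
    sigma: float = 0.05,
    seed: int = 0,
    read_length: int = 100,
) -> CoverageBins:
    """Negative-binomial binned read counts over a copy-number profile.

    Per-bin expectation is depth_factor * window / read_length * CN/2.
    ``sigma`` is log2-scale extra-dispersion, realised as a gamma mixing
    factor (gamma-Poisson = negative binomial); sigma = 0 gives Poisson.
    """
    if not 0 <= sigma:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    window = window_kb * 1000
    counts: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list] = {}
    for seg in profile.segments:
        by_chrom.setdefault(build.normalize_chrom(seg.chrom), []).append(seg)
    for chrom, segs in by_chrom.items():
        n_bins = build.lengths[chrom] // window
        starts = np.array([s.start for s in segs])
        totals = np.array([s.total_cn for s in segs], dtype=float)
        centers = (np.arange(n_bins) + 0.5) * window
        cn = totals[np.clip(np.searchsorted(starts, centers, side="right") - 1, 0, len(segs) - 1)]
        mean = depth_factor * window / read_length * cn / 2.0
        if sigma > 0:
            s_ln = sigma * math.log(2.0)
            shape = 1.0 / math.expm1(s_ln * s_ln)
            mean = mean * rng.gamma(shape, 1.0 / shape, size=n_bins)
        counts[chrom] = rng.poisson(mean).astype(float)
    return CoverageBins(sample_id=profile.sample_id, bin_width=window, counts=counts)


# ---------------------------------------------------------------------------
# RAD51 cell tables
# ---------------------------------------------------------------------------

def gen_cells(
    p_rad51: float,
    p_gh2ax: float,
    n_geminin: int,
    n_areas: int = 3,
    seed: int = 0,
    sample_id: str = "synthetic",
    n_geminin_neg: int = 0,
) -> SlideSample:
    """Per-cell immunofluorescence records with known positivity rates.

    Geminin-positive cells carry >= 5 RAD51 foci with probability
    ``p_rad51`` and gamma-H2AX positivity with probability ``p_gh2ax``;
    areas are assigned round-robin.
    """
    if not (0 <= p_rad51 <= 1 and 0 <= p_gh2ax <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    for i in range(n_geminin):
        positive = rng.random() < p_rad51
        foci = 5 + int(rng.poisson(3.0)) if positive else int(rng.integers(0, 5))
        cells.append(
            CellRecord(
                cell_id=f"{sample_id}-g{i:04d}",
                geminin_pos=True,
                rad51_foci=foci,
                gh2ax_pos=bool(rng.random() < p_gh2ax),
                area_id=f"A{i % n_areas + 1}",
            )
        )
    for i in range(n_geminin_neg):
        cells.append(
            CellRecord(
                cell_id=f"{sample_id}-n{i:04d}",
                geminin_pos=False,
                rad51_foci=int(rng.integers(0, 3)),
                gh2ax_pos=bool(rng.random() < p_gh2ax),
                area_id=f"A{i % n_areas + 1}",
            )
        )
    return SlideSample(sample_id=sample_id, cells=cells)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayModel:
    """Observation model for one assay, conditional on the latent state."""

    sensitivity: float
    specificity: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.missing_rate):
            if not 0 <= v <= 1:
                raise ValueError("rates must be probabilities")


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the simulated trial cohort.

    Defaults emulate a 100-patient first-line ovarian-cancer trial subset:
    ~59% latent HRD, a near-perfect reference assay with ~6% missingness,
    index assays with the observed sensitivity/specificity/missingness
    patterns, a designed PFS hazard ratio of 0.53 for HRD vs HRP,
    exponential progression times, uniform censoring, and response and
    covariate frequencies matching the published baseline table.
    """

    n_samples: int = 100
    hrd_fraction: float = 0.59
    assays: dict[str, AssayModel] = field(default_factory=lambda: {
        "MYRIAD": AssayModel(1.0, 1.0, 0.06),
        "LAB1": AssayModel(0.98, 0.84, 0.03),
        "LAB2": AssayModel(0.91, 0.85, 0.03),
        "LAB3": AssayModel(0.83, 0.33, 0.31),
    })
    pfs_hazard_ratio: float = 0.53  # HRD vs HRP
    median_pfs_hrp_months: float = 15.0
    censor_low_months: float = 24.0
    censor_high_months: float = 60.0
    response_rate_hrd: float = 0.82
    response_rate_hrp: float = 0.60
    not_evaluable_rate: float = 0.36
    p_age_lt65: float = 0.70
    p_ecog0: float = 0.80
    p_residual: tuple[float, float, float] = (0.36, 0.25, 0.39)
    p_figo_iii: float = 0.81

    def __post_init__(self) -> None:
        probs = (
            self.hrd_fraction, self.response_rate_hrd, self.response_rate_hrp,
            self.not_evaluable_rate, self.p_age_lt65, self.p_ecog0, self.p_figo_iii,
        ) + self.p_residual
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.p_residual) - 1) > 1e-9:
            raise ValueError("residual-disease probabilities must sum to 1")


def gen_cohort(
    spec: SynthSpec, seed: int
) -> tuple[dict[str, bool], dict[str, list[AssayCall]], pd.DataFrame]:
    """Simulate (latent truth, per-assay calls, outcome table).

    Progression times are exponential with the designed hazard ratio
    between true HRD and HRP strata; censoring is uniform.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    truth = {sid: bool(rng.random() < spec.hrd_fraction) for sid in sample_ids}

    calls: dict[str, list[AssayCall]] = {}
    for assay, model in spec.assays.items():
        out = []
        for sid in sample_ids:
            if rng.random() < model.missing_rate:
                out.append(AssayCall(sid, assay, "Missing", failure_reason="assay failed"))
                continue
            if truth[sid]:
                label = "HRD" if rng.random() < model.sensitivity else "HRP"
            else:
                label = "HRP" if rng.random() < model.specificity else "HRD"
            out.append(AssayCall(sid, assay, label))
        calls[assay] = out

    lam_hrp = math.log(2.0) / spec.median_pfs_hrp_months
    rows = []
    for sid in sample_ids:
        lam = lam_hrp * (spec.pfs_hazard_ratio if truth[sid] else 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(spec.censor_low_months, spec.censor_high_months)
        time = max(min(t_event, t_censor), 0.1)
        event = int(t_event <= t_censor)
        if rng.random() < spec.not_evaluable_rate:
            response = "not_evaluable"
        else:
            rr = spec.response_rate_hrd if truth[sid] else spec.response_rate_hrp
            if rng.random() < rr:
                response = "complete" if rng.random() < 31 / 46 else "partial"
            else:
                response = "stable" if rng.random() < 0.5 else "progression"
        rows.append(
            {
                "sample": sid,
                "time_months": round(time, 2),
                "event": event,
                "response": response,
                "age_group": "<65" if rng.random() < spec.p_age_lt65 else ">=65",
                "ecog": "0" if rng.random() < spec.p_ecog0 else "1-2",
                "residual_disease": ["none", "<=1cm", ">1cm"][
                    int(rng.choice(3, p=spec.p_residual))
                ],
                "figo_stage": "III" if rng.random() < spec.p_figo_iii else "IV",
                "true_hrd": truth[sid],
            }
        )
    return truth, calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-table fixtures
# ---------------------------------------------------------------------------

def fixture_table2() -> dict[str, ContingencyTable2x2]:
    """Complete-case cross-tabulations of each index assay vs the reference.

    Cells are (a, b, c, d) = (both HRD, index HRD/ref HRP, index HRP/ref
    HRD, both HRP); pairs with a missing call on either side are excluded
    and counted in ``n_excluded_missing`` (out of 100 samples).
    """
    return {
        "LAB1": ContingencyTable2x2(a=53, b=6, c=1, d=32, n_excluded_missing=8),
        "LAB2": ContingencyTable2x2(a=48, b=6, c=5, d=33, n_excluded_missing=8),
        "LAB3": ContingencyTable2x2(a=34, b=16, c=7, d=8, n_excluded_missing=35),
    }


def table2_margins() -> dict[str, dict[str, tuple[int, int, int]]]:
    """Printed 3x3 counts per assay: rows HRD/HRP/Missing x reference
    HRD/HRP/Missing.  Row and column sums total 100 samples."""
    return {
        "LAB1": {"HRD": (53, 6, 2), "HRP": (1, 32, 3), "Missing": (1, 1, 1)},
        "LAB2": {"HRD": (48, 6, 2), "HRP": (5, 33, 3), "Missing": (2, 0, 1)},
        "LAB3": {"HRD": (34, 16, 3), "HRP": (7, 8, 1), "Missing": (14, 15, 2)},
    }


def fixture_table2_calls(assay: str) -> tuple[list[AssayCall], list[AssayCall]]:
    """Synthetic per-sample call lists realizing one assay's printed 3x3
    cross-tabulation against the reference assay."""
    margins = table2_margins()[assay]
    ref_labels = ["HRD", "HRP", "Missing"]
    index_calls, ref_calls = [], []
    i = 0
    for row_label, counts in margins.items():
        for ref_label, count in zip(ref_labels, counts):
            for _ in range(count):
                sid = f"T{i + 1:03d}"
                i += 1
                index_calls.append(
                    AssayCall(sid, assay, row_label,
                              failure_reason="assay failed" if row_label == "Missing" else None)
                )
                ref_calls.append(
                    AssayCall(sid, "MYRIAD", ref_label,
                              failure_reason="assay failed" if ref_label == "Missing" else None)
                )
    return index_calls, ref_calls
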