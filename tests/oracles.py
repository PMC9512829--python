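"""Independent brute-force oracles used to validate the implementations.

The scar oracle materializes per-base copy-number state vectors at 0.1 Mb
resolution and applies the LOH/TAI/LST definitions literally on those
vectors; the segmentation oracles solve the penalized least-squares
objective by exhaustive scan / unpruned dynamic programming; the survival
oracle computes the Cox score test at beta = 0 by direct summation over
risk sets.
"""

from __future__ import annotations

import math

import numpy as np

GRID = 100_000


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _state_vectors(profile, build):
    """Per-chromosome (total, minor) vectors at GRID resolution; -1 = uncovered."""
    out = {}
    for chrom in build.chromosomes:
        n = build.lengths[chrom] // GRID
        out[chrom] = (np.full(n, -1, dtype=int), np.full(n, -1, dtype=int))
    for seg in profile.segments:
        chrom = build.normalize_chrom(seg.chrom)
        total = _round_half_away(seg.total_cn)
        minor = _round_half_away(seg.minor_cn)
        minor = min(minor, total - minor)
        t, m = out[chrom]
        t[seg.start // GRID : seg.end // GRID] = total
        m[seg.start // GRID : seg.end // GRID] = minor
    return out


def _true_runs(mask: np.ndarray):
    """(start, stop) half-open index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def scar_counts_per_base(profile, build, cfg):
    """LOH/TAI/LST counts from literal per-base application of the rules."""
    vectors = _state_vectors(profile, build)
    loh = tai = lst = 0
    for chrom, (total, minor) in vectors.items():
        n = len(total)
        cs, ce = build.centromere(chrom)
        cen0, cen1 = cs // GRID, ce // GRID

        covered = total >= 0
        loh_mask = covered & (minor == 0) & (total >= 1)
        for s, e in _true_runs(loh_mask):
            whole_chrom = s == 0 and e == n
            if (e - s) * GRID > cfg.loh_min_len and not whole_chrom:
                loh += 1

        ai_mask = covered & (minor != total - minor)
        for s, e in _true_runs(ai_mask):
            touches_end = s == 0 or e == n
            crosses_cen = s < cen1 and e > cen0
            if touches_end and not crosses_cen and (e - s) * GRID > cfg.tai_min_len:
                tai += 1

        for arm_lo, arm_hi in ((0, cen0), (cen1, n)):
            lst += _lst_on_arm(total[arm_lo:arm_hi], minor[arm_lo:arm_hi], cfg)
    return loh, tai, lst


def _lst_on_arm(total, minor, cfg):
    smooth = cfg.lst_smooth_len // GRID
    min_seg = cfg.lst_min_seg // GRID
    # run-length encode states
    runs = []  # (start, stop, state)
    i = 0
    n = len(total)
    while i < n:
        j = i
        state = (total[i], minor[i])
        while j < n and (total[j], minor[j]) == state:
            j += 1
        runs.append([i, j, j - i, state])
        i = j
    runs = [r for r in runs if r[3][0] >= 0]  # drop uncovered
    kept = [r for r in runs if r[2] >= smooth]
    # re-merge equal states across smoothed-away slivers
    merged = []
    for start, stop, length, state in kept:
        if merged and merged[-1][3] == state and start - merged[-1][1] <= smooth:
            merged[-1][1] = stop
            merged[-1][2] += length
        else:
            merged.append([start, stop, length, state])
    count = 0
    for left, right in zip(merged, merged[1:]):
        gap = right[0] - left[1]
        if (
            gap <= smooth
            and left[3] != right[3]
            and left[2] >= min_seg
            and right[2] >= min_seg
        ):
            count += 1
    return count


# ---------------------------------------------------------------------------
# segmentation oracles
# ---------------------------------------------------------------------------

def best_single_changepoint(y: np.ndarray) -> int:
    """Exhaustive least-squares scan for one changepoint position."""
    y = np.asarray(y, dtype=float)
    best, arg = np.inf, 1
    for k in range(1, len(y)):
        sse = ((y[:k] - y[:k].mean()) ** 2).sum() + ((y[k:] - y[k:].mean()) ** 2).sum()
        if sse < best:
            best, arg = sse, k
    return arg


def dp_segment(y: np.ndarray, penalty: float) -> list[int]:
    """Unpruned O(n^2) penalized least-squares DP; returns segment ends."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(s, t):
        d = cum[t] - cum[s]
        return (cum2[t] - cum2[s]) - d * d / (t - s)

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        for s in range(t):
            v = F[s] + penalty + cost(s, t)
            if v < F[t]:
                F[t] = v
                prev[t] = s
    ends = []
    t = n
    while t > 0:
        ends.append(t)
        t = prev[t]
    return ends[::-1]


# ---------------------------------------------------------------------------
# survival oracles
# ---------------------------------------------------------------------------

def km_product_limit(times, events):
    """Hand product-limit table: (event_time, survival) pairs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / at_risk
        out.append((t, s))
    return out


def cox_score_test_at_null(times, events, group):
    """Score test statistic U(0)^2 / I(0) for one binary covariate.

    Valid for untied event times; identical to the two-group log-rank
    chi-square there.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(group, dtype=float)
    u = 0.0
    info = 0.0
    for t in sorted(times[events == 1]):
        risk = times >= t
        xbar = x[risk].mean()
        i = np.flatnonzero((times == t) & (events == 1))[0]
        u += x[i] - xbar
        info += (x[risk] ** 2).mean() - xbar**2
    return u * u / info
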