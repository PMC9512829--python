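"""Functional HRD scoring from RAD51 immunofluorescence cell counts.

The RAD51 score is the percentage of geminin-positive (S/G2-phase) tumor
cells with five or more RAD51 nuclear foci.  Two QC gates precede scoring:
a slide fails with fewer than 40 geminin-positive cells (not enough cycling
tumor cells) or when fewer than 25% of geminin-positive cells carry gamma-
H2AX foci (not enough endogenous double-strand-break damage to license
RAD51 focus formation).  Samples passing QC are called HRD when the score
is <= 10% and HRP above.  Failure conditions use strict inequalities, so
exactly 40 cells or exactly 25% gamma-H2AX pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_core import SlideSample

__all__ = [
    "Rad51Config",
    "Rad51Result",
    "qc_slide",
    "rad51_score",
    "classify_rad51",
    "subsample_cells",
    "score_slide",
]


@dataclass(frozen=True)
class Rad51Config:
    foci_min: int = 5
    score_cutoff_pct: float = 10.0
    min_geminin_cells: int = 40
    min_gh2ax_pct: float = 25.0
    target_cells: int = 100
    min_areas: int = 3

    def __post_init__(self) -> None:
        for name in (
            "foci_min", "score_cutoff_pct", "min_geminin_cells",
            "min_gh2ax_pct", "target_cells", "min_areas",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Rad51Result:
    sample_id: str
    n_geminin: int
    gh2ax_pct: float | None
    rad51_score_pct: float | None
    qc: str  # pass | fail_low_gh2ax | fail_few_cells | fail_no_tumor
    label: str  # HRD | HRP | Inconclusive


def qc_slide(sample: SlideSample, cfg: Rad51Config = Rad51Config()) -> str:
    """QC gates, evaluated in order: no tumor, too few cells, low gamma-H2AX."""
    if not sample.cells:
        return "fail_no_tumor"
    gem = sample.geminin_positive()
    if len(gem) < cfg.min_geminin_cells:
        return "fail_few_cells"
    gh2ax_pct = 100.0 * sum(c.gh2ax_pos for c in gem) / len(gem)
    if gh2ax_pct < cfg.min_gh2ax_pct:
        return "fail_low_gh2ax"
    return "pass"


def rad51_score(sample: SlideSample, cfg: Rad51Config = Rad51Config()) -> float:
    """Percentage of geminin-positive cells with >= foci_min RAD51 foci.

    Geminin-negative cells are ignored entirely.  Raises when called on a
    slide that fails QC.
    """
    qc = qc_slide(sample, cfg)
    if qc != "pass":
        raise ValueError(f"sample {sample.sample_id}: cannot score a slide with QC status {qc}")
    gem = sample.geminin_positive()
    return 100.0 * sum(c.rad51_foci >= cfg.foci_min for c in gem) / len(gem)


def classify_rad51(score_pct: float, cfg: Rad51Config = Rad51Config()) -> str:
    """HRD when the score is at or below the cutoff (<= 10%), else HRP."""
    if not 0.0 <= score_pct <= 100.0:
        raise ValueError(f"score must be a percentage in [0, 100], got {score_pct}")
    return "HRD" if score_pct <= cfg.score_cutoff_pct else "HRP"


def subsample_cells(
    sample: SlideSample, cfg: Rad51Config = Rad51Config(), seed: int = 0
) -> SlideSample:
    """Cap the analysis at ``target_cells`` geminin-positive cells.

    When more are available, exactly ``target_cells`` are drawn without
    replacement by round-robin over areas, so at least ``min_areas`` areas
    are represented whenever that many exist.  Deterministic for fixed seed.
    With fewer than ``min_areas`` areas the draw proceeds with a warning.
    """
    gem = sample.geminin_positive()
    areas = sorted({c.area_id for c in gem})
    if len(areas) < cfg.min_areas:
        warnings.warn(
            f"sample {sample.sample_id}: only {len(areas)} area(s) available "
            f"(target >= {cfg.min_areas}); proceeding",
            stacklevel=2,
        )
    if len(gem) <= cfg.target_cells:
        return sample
    rng = np.random.default_rng(seed)
    by_area = {a: [c for c in gem if c.area_id == a] for a in areas}
    for a in areas:
        rng.shuffle(by_area[a])
    chosen = []
    while len(chosen) < cfg.target_cells:
        for a in areas:
            if by_area[a] and len(chosen) < cfg.target_cells:
                chosen.append(by_area[a].pop())
    chosen.sort(key=lambda c: c.cell_id)
    return replace(sample, cells=chosen)


def score_slide(
    sample: SlideSample, cfg: Rad51Config = Rad51Config(), seed: int = 0,
    subsample: bool = True,
) -> Rad51Result:
    """Full LAB3-style pipeline: QC gates, optional capping, score, label."""
    qc = qc_slide(sample, cfg)
    gem = sample.geminin_positive()
    gh2ax_pct = (
        100.0 * sum(c.gh2ax_pos for c in gem) / len(gem) if gem else None
    )
    if qc != "pass":
        return Rad51Result(
            sample_id=sample.sample_id, n_geminin=len(gem), gh2ax_pct=gh2ax_pct,
            rad51_score_pct=None, qc=qc, label="Inconclusive",
        )
    scored = subsample_cells(sample, cfg, seed) if subsample else sample
    # QC was established on the full slide; score the (possibly capped) cells
    scored_gem = scored.geminin_positive()
    score = 100.0 * sum(c.rad51_foci >= cfg.foci_min for c in scored_gem) / len(scored_gem)
    return Rad51Result(
        sample_id=sample.sample_id, n_geminin=len(gem), gh2ax_pct=gh2ax_pct,
        rad51_score_pct=score, qc=qc, label=classify_rad51(score, cfg),
    )
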