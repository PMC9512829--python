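"""Diagnostic-concordance statistics for paired binary assay calls.

Everything operates on complete cases: sample pairs in which both the index
assay and the reference assay produced a definitive HRD/HRP call.  The 2x2
table convention is

    a = index HRD & reference HRD        b = index HRD & reference HRP
    c = index HRP & reference HRD        d = index HRP & reference HRP

Agreement rate is (a + d) / n with an exact (Clopper-Pearson) binomial CI.
Cohen's kappa is (p_o - p_e) / (1 - p_e) with the large-sample asymptotic
standard error; its point estimate is banded with the conventional
interpretation scale (slight / fair / moderate / substantial / almost
perfect).  Sensitivity and specificity treat the reference assay as truth
and carry exact CIs.  A planning helper inverts the kappa CI half-width for
the required sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "AssayCall",
    "ContingencyTable2x2",
    "KappaResult",
    "ConcordanceReport",
    "build_contingency",
    "agreement_rate",
    "cohens_kappa",
    "kappa_band",
    "sensitivity_specificity",
    "clopper_pearson",
    "kappa_sample_size",
    "cross_classify",
    "concordance_report",
]


@dataclass(frozen=True)
class AssayCall:
    sample_id: str
    assay: str
    label: str  # HRD | HRP | Missing
    score: float | None = None
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.label not in {"HRD", "HRP", "Missing"}:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "Missing") != (self.failure_reason is not None):
            raise ValueError("label must be Missing iff a failure reason is set")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    band: str
    p_observed: float
    p_expected: float


@dataclass(frozen=True)
class ConcordanceReport:
    table: ContingencyTable2x2
    agreement: float
    agreement_ci: tuple[float, float]
    kappa: KappaResult
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]


def build_contingency(
    index_calls: list[AssayCall], ref_calls: list[AssayCall]
) -> ContingencyTable2x2:
    """Cross-tabulate two call sets on the complete cases.

    Pairs in which either call is Missing (or a sample is present in only
    one set) are excluded and counted in ``n_excluded_missing``.
    """
    index = {c.sample_id: c for c in index_calls}
    ref = {c.sample_id: c for c in ref_calls}
    universe = set(index) | set(ref)
    a = b = c_ = d = excluded = 0
    for sid in universe:
        ic, rc = index.get(sid), ref.get(sid)
        if ic is None or rc is None or ic.label == "Missing" or rc.label == "Missing":
            excluded += 1
            continue
        if ic.label == "HRD" and rc.label == "HRD":
            a += 1
        elif ic.label == "HRD":
            b += 1
        elif rc.label == "HRD":
            c_ += 1
        else:
            d += 1
    if a + b + c_ + d == 0:
        raise ValueError("no complete cases: every pair has a missing call")
    return ContingencyTable2x2(a=a, b=b, c=c_, d=d, n_excluded_missing=excluded)


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI via beta-quantile equivalence.

    Lower bound is 0 when x = 0 and the upper bound is 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - conf_level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return (lower, upper)


def agreement_rate(
    t: ContingencyTable2x2, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Observed agreement (a + d)/n with an exact binomial CI."""
    if t.n == 0:
        raise ValueError("empty table")
    x = t.a + t.d
    return x / t.n, clopper_pearson(x, t.n, conf_level)


def kappa_band(kappa: float) -> str:
    """Conventional interpretation bands for Cohen's kappa."""
    if kappa < 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_kappa(t: ContingencyTable2x2, conf_level: float = 0.95) -> KappaResult:
    """Chance-corrected agreement with asymptotic SE and Wald CI.

    kappa = (p_o - p_e) / (1 - p_e) where p_o = (a + d)/n and p_e is the
    product of the marginal rates.  SE is the large-sample approximation
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)); the CI is clipped to [-1, 1].
    """
    n = t.n
    if n == 0:
        raise ValueError("empty table")
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)
    if p_e >= 1.0:
        raise ValueError("degenerate margins: expected agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    ci = (max(kappa - z * se, -1.0), min(kappa + z * se, 1.0))
    return KappaResult(
        kappa=kappa, se=se, ci=ci, band=kappa_band(kappa),
        p_observed=p_o, p_expected=p_e,
    )


def sensitivity_specificity(
    t: ContingencyTable2x2, conf_level: float = 0.95
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Sensitivity a/(a+c) and specificity d/(b+d) against the reference,
    each with an exact Clopper-Pearson CI."""
    if t.a + t.c == 0 or t.b + t.d == 0:
        raise ValueError("reference margin is degenerate (no HRD or no HRP cases)")
    sens = t.a / (t.a + t.c)
    spec = t.d / (t.b + t.d)
    return {
        "sensitivity": (sens, clopper_pearson(t.a, t.a + t.c, conf_level)),
        "specificity": (spec, clopper_pearson(t.d, t.b + t.d, conf_level)),
    }


def kappa_sample_size(
    kappa_sd: float, ci_width: float, conf_level: float = 0.95
) -> int:
    """Samples needed so a two-sided kappa CI has the requested full width.

    n = ceil( (z * sd / (width / 2))^2 ).  With sd 0.60 and width 0.25 at
    95% confidence this gives 89.
    """
    if ci_width <= 0 or kappa_sd <= 0:
        raise ValueError("ci_width and kappa_sd must be positive")
    z = stats.norm.ppf(0.5 + conf_level / 2)
    return math.ceil((z * kappa_sd / (ci_width / 2)) ** 2)


@dataclass
class CrossClassification:
    both_hrd: list[str] = field(default_factory=list)
    a_hrd_b_hrp: list[str] = field(default_factory=list)
    a_hrp_b_hrd: list[str] = field(default_factory=list)
    both_hrp: list[str] = field(default_factory=list)


def cross_classify(
    calls_a: list[AssayCall], calls_b: list[AssayCall]
) -> CrossClassification:
    """Partition complete cases into the four joint HRD/HRP groups."""
    a_map = {c.sample_id: c for c in calls_a}
    b_map = {c.sample_id: c for c in calls_b}
    shared = set(a_map) & set(b_map)
    if not shared:
        raise ValueError("disjoint sample sets")
    out = CrossClassification()
    for sid in sorted(shared):
        la, lb = a_map[sid].label, b_map[sid].label
        if "Missing" in (la, lb):
            continue
        if la == "HRD" and lb == "HRD":
            out.both_hrd.append(sid)
        elif la == "HRD":
            out.a_hrd_b_hrp.append(sid)
        elif lb == "HRD":
            out.a_hrp_b_hrd.append(sid)
        else:
            out.both_hrp.append(sid)
    return out


def concordance_report(
    t: ContingencyTable2x2, conf_level: float = 0.95
) -> ConcordanceReport:
    """All Table-3-style metrics for one index assay against the reference."""
    agree, agree_ci = agreement_rate(t, conf_level)
    ss = sensitivity_specificity(t, conf_level)
    return ConcordanceReport(
        table=t,
        agreement=agree, agreement_ci=agree_ci,
        kappa=cohens_kappa(t, conf_level),
        sensitivity=ss["sensitivity"][0], sensitivity_ci=ss["sensitivity"][1],
        specificity=ss["specificity"][0], specificity_ci=ss["specificity"][1],
    )
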