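"""BRCA1/2 driver filtering, per-sample status, and mutation-level concordance.

Variant classification labels arrive as input annotations (database lookup
is upstream); only pathogenic and likely-pathogenic variants are retained
as drivers.  A sample is BRCA-mutated when any retained variant falls in
BRCA1 or BRCA2.  Mutation-level concordance between two assays compares the
retained variant sets per sample on the complete cases: samples agree only
when the sets are identical, and "same status, different mutation" pairs
are tallied separately (they still count as disagreement in the headline
agreement rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .concordance_stats import ContingencyTable2x2, cohens_kappa
from .io_core import VariantRecord

__all__ = [
    "BrcaStatus",
    "MutationConcordance",
    "DRIVER_CLASSES",
    "filter_drivers",
    "brca_status",
    "group_by_sample",
    "mutation_concordance",
]

DRIVER_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})
BRCA_GENES = frozenset({"BRCA1", "BRCA2"})


@dataclass(frozen=True)
class BrcaStatus:
    sample_id: str
    status: str  # mutated | wild_type
    retained: tuple[VariantRecord, ...] = ()

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(v.key for v in self.retained)


@dataclass
class MutationConcordance:
    n: int
    n_agree: int
    n_status_mismatch: int
    n_different_mutation: int  # same mutated/WT status, different variants
    agreement_rate: float
    kappa: float
    per_sample: dict[str, str] = field(default_factory=dict)


def filter_drivers(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep pathogenic / likely-pathogenic variants; drop benign, likely
    benign, passenger, and VUS.  Idempotent."""
    return [v for v in variants if v.classification in DRIVER_CLASSES]


def brca_status(sample_id: str, retained: list[VariantRecord]) -> BrcaStatus:
    """Mutated iff any retained driver variant lies in BRCA1/BRCA2."""
    brca = tuple(v for v in retained if v.gene.upper() in BRCA_GENES)
    return BrcaStatus(
        sample_id=sample_id,
        status="mutated" if brca else "wild_type",
        retained=brca,
    )


def group_by_sample(variants: list[VariantRecord]) -> dict[str, BrcaStatus]:
    """Driver-filter a variant table and derive per-sample BRCA status."""
    by_sample: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    return {
        sid: brca_status(sid, filter_drivers(vs)) for sid, vs in by_sample.items()
    }


def mutation_concordance(
    calls_a: dict[str, BrcaStatus], calls_b: dict[str, BrcaStatus]
) -> MutationConcordance:
    """Mutation-level agreement between two assays on complete cases.

    Per shared sample: agree iff the retained BRCA variant-key sets are
    identical (both empty counts as agreement).  Pairs with the same
    mutated/WT status but different variants are reported separately and
    count as disagreement.  Cohen's kappa is computed on the binary
    mutated/wild-type labels.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no samples shared between the two call sets")
    n_agree = n_diff_mut = n_status = 0
    a = b = c = d = 0  # mutated/mutated, mut/WT, WT/mut, WT/WT on labels
    per_sample: dict[str, str] = {}
    for sid in shared:
        sa, sb = calls_a[sid], calls_b[sid]
        if sa.status == "mutated" and sb.status == "mutated":
            a += 1
        elif sa.status == "mutated":
            b += 1
        elif sb.status == "mutated":
            c += 1
        else:
            d += 1
        if sa.keys == sb.keys:
            n_agree += 1
            per_sample[sid] = "agree"
        elif sa.status == sb.status:
            n_diff_mut += 1
            per_sample[sid] = "different_mutation"
        else:
            n_status += 1
            per_sample[sid] = "status_mismatch"
    n = len(shared)
    table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
    kappa = cohens_kappa(table).kappa
    return MutationConcordance(
        n=n, n_agree=n_agree, n_status_mismatch=n_status,
        n_different_mutation=n_diff_mut,
        agreement_rate=n_agree / n, kappa=kappa, per_sample=per_sample,
    )
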