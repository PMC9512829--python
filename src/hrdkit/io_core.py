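"""Readers and writers for the tabular formats the toolkit consumes.

No science lives here.  Each reader validates and rejects malformed rows
(with row numbers) rather than silently repairing them, and each format has
a matching writer so write-then-read is the identity.

Coordinate conventions: segment files use the SEG dialect with 1-based
inclusive coordinates; internally everything is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .builds import GenomeBuild

__all__ = [
    "AlleleSpecificSegment",
    "SegmentProfile",
    "VariantRecord",
    "CellRecord",
    "SlideSample",
    "CoverageBins",
    "SampleTable",
    "CLASSIFICATIONS",
    "read_segments",
    "write_segments",
    "read_variant_table",
    "write_variant_table",
    "read_cell_table",
    "write_cell_table",
    "read_bins",
    "write_bins",
    "read_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleSpecificSegment:
    """One allele-specific copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: end must be > start"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """Per-sample allele-specific segment profile (sorted, non-overlapping)."""

    sample_id: str
    segments: list[AlleleSpecificSegment]
    ploidy: float | None = None
    purity: float | None = None

    def sorted(self) -> "SegmentProfile":
        segs = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        return replace(self, segments=segs)

    def validate(self, build: GenomeBuild | None = None) -> "SegmentProfile":
        """Check ordering / overlap (and coordinates against a build)."""
        prof = self.sorted()
        last: AlleleSpecificSegment | None = None
        for seg in prof.segments:
            if build is not None:
                chrom = build.normalize_chrom(seg.chrom)
                if seg.end > build.lengths[chrom]:
                    raise ValueError(
                        f"sample {self.sample_id}: segment "
                        f"{seg.chrom}:{seg.start}-{seg.end} exceeds chromosome "
                        f"length {build.lengths[chrom]}"
                    )
            if last is not None and seg.chrom == last.chrom and seg.start < last.end:
                raise ValueError(
                    f"sample {self.sample_id}: overlapping segments "
                    f"{seg.chrom}:{last.start}-{last.end} and "
                    f"{seg.chrom}:{seg.start}-{seg.end}"
                )
            last = seg
        return prof


CLASSIFICATIONS = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "passenger"}
)

# tokens seen in ClinVar-style CLNSIG fields and free-text tables
_CLASSIFICATION_ALIASES = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "vus": "vus",
    "uncertain_significance": "vus",
    "uncertain significance": "vus",
    "likely_benign": "likely_benign",
    "likely benign": "likely_benign",
    "benign": "benign",
    "passenger": "passenger",
}


def normalize_classification(token: str) -> str:
    key = token.strip().lower().replace("-", "_")
    try:
        return _CLASSIFICATION_ALIASES[key]
    except KeyError:
        try:
            return _CLASSIFICATION_ALIASES[key.replace("_", " ")]
        except KeyError:
            raise ValueError(
                f"unknown classification token {token!r}; expected one of "
                f"{sorted(CLASSIFICATIONS)}"
            ) from None


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic/germline variant for one sample."""

    sample_id: str
    gene: str
    hgvs: str
    classification: str
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.origin not in {"somatic", "germline", "unknown"}:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def key(self) -> str:
        """Normalized variant key: GENE:c-string with whitespace stripped."""
        return f"{self.gene.upper()}:{''.join(self.hgvs.split())}"


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    geminin_pos: bool
    rad51_foci: int
    gh2ax_pos: bool
    area_id: str

    def __post_init__(self) -> None:
        if self.rad51_foci < 0:
            raise ValueError(f"cell {self.cell_id}: negative RAD51 foci count")


@dataclass
class SlideSample:
    """Per-cell immunofluorescence records for one tumor section."""

    sample_id: str
    cells: list[CellRecord]

    def geminin_positive(self) -> list[CellRecord]:
        return [c for c in self.cells if c.geminin_pos]


@dataclass
class CoverageBins:
    """Fixed-width binned read counts per chromosome for one sample."""

    sample_id: str
    bin_width: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"chromosome {chrom}: negative counts")
            self.counts[chrom] = arr

    def total_span(self) -> int:
        return self.bin_width * sum(len(v) for v in self.counts.values())


@dataclass
class SampleTable:
    """Manifest mapping sample ids to per-assay inputs."""

    assay: str
    paths: dict[str, str | Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.paths)) != len(self.paths):
            raise ValueError("sample ids must be unique per assay")


# ---------------------------------------------------------------------------
# segments (SEG dialect)
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


def _parse_header(line: str, required: list[str], path: str) -> dict[str, int]:
    cols = line.rstrip("\n").split("\t")
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return {c: cols.index(c) for c in cols}


def read_segments(path: str | Path, build: GenomeBuild) -> dict[str, SegmentProfile]:
    """Read a SEG-dialect TSV into per-sample profiles.

    Input coordinates are 1-based inclusive and converted to 0-based
    half-open.  Chromosome names are normalized to the build's naming.
    """
    path = Path(path)
    per_sample: dict[str, list[AlleleSpecificSegment]] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, header required")
        idx = _parse_header(header, _SEG_COLUMNS, str(path))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                sample = f[idx["sample"]]
                chrom = build.normalize_chrom(f[idx["chrom"]])
                start1 = int(f[idx["start"]])
                end1 = int(f[idx["end"]])
                total_cn = float(f[idx["total_cn"]])
                minor_cn = float(f[idx["minor_cn"]])
            except (IndexError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {lineno}: {exc}") from None
            if end1 < start1:
                raise ValueError(
                    f"{path}, row {lineno}: end ({end1}) < start ({start1})"
                )
            if start1 < 1:
                raise ValueError(f"{path}, row {lineno}: start must be >= 1")
            seg = AlleleSpecificSegment(
                chrom=chrom, start=start1 - 1, end=end1,
                total_cn=total_cn, minor_cn=minor_cn,
            )
            per_sample.setdefault(sample, []).append(seg)
    return {
        sid: SegmentProfile(sample_id=sid, segments=segs).validate(build)
        for sid, segs in per_sample.items()
    }


def write_segments(path: str | Path, profiles: dict[str, SegmentProfile]) -> None:
    """Write profiles back to the SEG dialect (1-based inclusive)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for prof in profiles.values():
            for s in prof.sorted().segments:
                fh.write(
                    f"{prof.sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                    f"{_fmt_cn(s.total_cn)}\t{_fmt_cn(s.minor_cn)}\n"
                )


def _fmt_cn(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# variants (VCF or TSV)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["sample", "gene", "hgvs", "classification", "origin"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read variants from a VCF (INFO keys GENE/CLNSIG) or an annotated TSV."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        return _read_variant_vcf(path)
    return _read_variant_tsv(path)


def _read_variant_vcf(path: Path) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        default_sample = samples[0] if samples else path.stem
        for n, rec in enumerate(vcf.fetch(), start=1):
            info = dict(rec.info)
            if "CLNSIG" not in info:
                raise ValueError(f"{path}: record {n} ({rec.chrom}:{rec.pos}) lacks CLNSIG")
            if "GENE" not in info:
                raise ValueError(f"{path}: record {n} ({rec.chrom}:{rec.pos}) lacks GENE")
            clnsig = info["CLNSIG"]
            if isinstance(clnsig, tuple):
                clnsig = clnsig[0]
            gene = info["GENE"]
            if isinstance(gene, tuple):
                gene = gene[0]
            hgvs = info.get("HGVS", f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alts[0] if rec.alts else '.'}")
            if isinstance(hgvs, tuple):
                hgvs = hgvs[0]
            origin = info.get("ORIGIN", "unknown")
            if isinstance(origin, tuple):
                origin = origin[0]
            records.append(
                VariantRecord(
                    sample_id=str(info.get("SAMPLE", default_sample)),
                    gene=str(gene),
                    hgvs=str(hgvs),
                    classification=normalize_classification(str(clnsig)),
                    origin=str(origin),
                )
            )
    return records


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with path.open() as fh:
        header = fh.readline()
        idx = _parse_header(header, _VARIANT_COLUMNS, str(path))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                records.append(
                    VariantRecord(
                        sample_id=f[idx["sample"]],
                        gene=f[idx["gene"]],
                        hgvs=f[idx["hgvs"]],
                        classification=normalize_classification(f[idx["classification"]]),
                        origin=f[idx["origin"]],
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, row {lineno}: {exc}") from None
    return records


def write_variant_table(path: str | Path, records: list[VariantRecord]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.gene}\t{r.hgvs}\t{r.classification}\t{r.origin}\n")


# ---------------------------------------------------------------------------
# per-cell immunofluorescence tables
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["sample", "cell_id", "geminin_pos", "rad51_foci", "gh2ax_pos", "area_id"]


def _parse_bool01(token: str, lineno: int, path: Path) -> bool:
    if token not in {"0", "1"}:
        raise ValueError(f"{path}, row {lineno}: expected 0/1, got {token!r}")
    return token == "1"


def read_cell_table(path: str | Path) -> dict[str, SlideSample]:
    path = Path(path)
    per_sample: dict[str, list[CellRecord]] = {}
    with path.open() as fh:
        header = fh.readline()
        idx = _parse_header(header, _CELL_COLUMNS, str(path))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                foci = int(f[idx["rad51_foci"]])
                if foci < 0:
                    raise ValueError(f"negative RAD51 foci count ({foci})")
                rec = CellRecord(
                    cell_id=f[idx["cell_id"]],
                    geminin_pos=_parse_bool01(f[idx["geminin_pos"]], lineno, path),
                    rad51_foci=foci,
                    gh2ax_pos=_parse_bool01(f[idx["gh2ax_pos"]], lineno, path),
                    area_id=f[idx["area_id"]],
                )
            except (IndexError, ValueError) as exc:
                msg = str(exc)
                if f"row {lineno}" not in msg:
                    msg = f"{path}, row {lineno}: {msg}"
                raise ValueError(msg) from None
            per_sample.setdefault(f[idx["sample"]], []).append(rec)
    return {sid: SlideSample(sample_id=sid, cells=cells) for sid, cells in per_sample.items()}


def write_cell_table(path: str | Path, samples: dict[str, SlideSample]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_CELL_COLUMNS) + "\n")
        for s in samples.values():
            for c in s.cells:
                fh.write(
                    f"{s.sample_id}\t{c.cell_id}\t{int(c.geminin_pos)}\t"
                    f"{c.rad51_foci}\t{int(c.gh2ax_pos)}\t{c.area_id}\n"
                )


# ---------------------------------------------------------------------------
# coverage bins
# ---------------------------------------------------------------------------

_BIN_COLUMNS = ["sample", "chrom", "start", "count"]


def read_bins(path: str | Path) -> dict[str, CoverageBins]:
    """Read binned read counts: TSV sample, chrom, start (0-based bp), count.

    The bin width is inferred from consecutive starts and must be uniform.
    """
    path = Path(path)
    raw: dict[str, dict[str, list[tuple[int, float]]]] = {}
    with path.open() as fh:
        header = fh.readline()
        idx = _parse_header(header, _BIN_COLUMNS, str(path))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                sample, chrom = f[idx["sample"]], f[idx["chrom"]]
                start, count = int(f[idx["start"]]), float(f[idx["count"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, row {lineno}: {exc}") from None
            if count < 0:
                raise ValueError(f"{path}, row {lineno}: negative count")
            raw.setdefault(sample, {}).setdefault(chrom, []).append((start, count))

    out: dict[str, CoverageBins] = {}
    for sample, chroms in raw.items():
        width: int | None = None
        counts: dict[str, np.ndarray] = {}
        for chrom, rows in chroms.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            diffs = np.unique(np.diff(starts)) if len(starts) > 1 else np.array([])
            if len(diffs) > 1 or (width is not None and len(diffs) == 1 and diffs[0] != width):
                raise ValueError(f"{path}: non-uniform bin width for sample {sample}, chromosome {chrom}")
            if len(diffs) == 1:
                width = int(diffs[0])
            counts[chrom] = np.array([r[1] for r in rows], dtype=float)
        if width is None:
            raise ValueError(f"{path}: cannot infer bin width for sample {sample} (single bin per chromosome)")
        out[sample] = CoverageBins(sample_id=sample, bin_width=width, counts=counts)
    return out


def write_bins(path: str | Path, samples: dict[str, CoverageBins]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_BIN_COLUMNS) + "\n")
        for s in samples.values():
            for chrom, arr in s.counts.items():
                for i, count in enumerate(arr):
                    c = int(count) if float(count).is_integer() else count
                    fh.write(f"{s.sample_id}\t{chrom}\t{i * s.bin_width}\t{c}\n")


# ---------------------------------------------------------------------------
# cohort outcome tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "sample", "time_months", "event", "response",
    "age_group", "ecog", "residual_disease", "figo_stage",
]

_COHORT_VOCAB = {
    "response": {"complete", "partial", "stable", "progression", "not_evaluable"},
    "age_group": {"<65", ">=65"},
    "ecog": {"0", "1-2"},
    "residual_disease": {"none", "<=1cm", ">1cm"},
    "figo_stage": {"III", "IV"},
}


def read_cohort(path: str | Path):
    """Read a cohort outcome table into a validated pandas DataFrame."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["time_months"] = df["time_months"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time_months"] <= 0).any():
        bad = df.index[df["time_months"] <= 0][0]
        raise ValueError(f"{path}, row {bad + 2}: time must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event flag must be 0/1")
    for col, vocab in _COHORT_VOCAB.items():
        bad = set(df[col]) - vocab
        if bad:
            raise ValueError(f"{path}: column {col} has unknown levels {sorted(bad)}")
    return df


def write_cohort(path: str | Path, df) -> None:
    out = df[COHORT_COLUMNS].copy()
    if (out["time_months"] == out["time_months"].round()).all():
        out["time_months"] = out["time_months"].astype(int)
    out.to_csv(path, sep="\t", index=False)
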