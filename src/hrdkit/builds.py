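"""Genome builds: chromosome lengths and centromere intervals.

Scar components need chromosome ends (telomeres, implied at coordinate 0 and
at the chromosome length) and centromere intervals (telomeric-allelic
imbalance must not cross the centromere; large-scale transitions are counted
per arm).  All science operations take the build as an explicit parameter;
:func:`default_build` ships a human-like set of 22 autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeBuild", "default_build", "compact_build"]

# Human autosome lengths and centromere (acen) intervals, in Mb, rounded to
# a 0.1 Mb grid.  Scar thresholds operate at the 10 Mb scale, so the grid
# rounding is immaterial to scoring.
_HUMAN_AUTOSOMES_MB = {
    "1": (249.3, 121.5, 124.5),
    "2": (243.2, 92.3, 95.3),
    "3": (198.0, 90.5, 93.5),
    "4": (191.2, 49.7, 52.7),
    "5": (180.9, 46.4, 49.4),
    "6": (171.1, 58.8, 61.8),
    "7": (159.1, 58.1, 61.1),
    "8": (146.4, 43.8, 46.8),
    "9": (141.2, 47.4, 50.4),
    "10": (135.5, 39.3, 42.3),
    "11": (135.0, 51.6, 54.6),
    "12": (133.9, 34.9, 37.9),
    "13": (115.2, 16.0, 19.0),
    "14": (107.3, 16.0, 19.0),
    "15": (102.5, 17.0, 20.0),
    "16": (90.4, 35.3, 38.3),
    "17": (81.2, 22.3, 25.3),
    "18": (78.1, 15.5, 18.5),
    "19": (59.1, 24.7, 27.7),
    "20": (63.0, 26.4, 29.4),
    "21": (48.1, 11.3, 14.3),
    "22": (51.3, 13.0, 16.0),
}


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths (bp) and centromere intervals (bp, half-open).

    Telomere positions are implied: coordinate 0 and the chromosome length.
    """

    name: str
    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be > 0")
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.lengths:
                raise ValueError(f"centromere for unknown chromosome {chrom}")
            if not (0 < cs < ce < self.lengths[chrom]):
                raise ValueError(
                    f"chromosome {chrom}: centromere ({cs}, {ce}) must lie "
                    f"strictly inside (0, {self.lengths[chrom]})"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def normalize_chrom(self, chrom: str) -> str:
        """Map 'chr1' / '1' style names onto this build's naming.

        Raises KeyError for chromosomes absent from the build.
        """
        if chrom in self.lengths:
            return chrom
        stripped = chrom.removeprefix("chr")
        if stripped in self.lengths:
            return stripped
        prefixed = "chr" + chrom
        if prefixed in self.lengths:
            return prefixed
        raise KeyError(f"chromosome {chrom!r} not in build {self.name!r}")

    def centromere(self, chrom: str) -> tuple[int, int]:
        try:
            return self.centromeres[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} has no centromere annotation in "
                f"build {self.name!r}"
            ) from None

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        """p and q arm intervals (half-open, bp), centromere excluded."""
        cs, ce = self.centromere(chrom)
        return [(0, cs), (ce, self.lengths[chrom])]

    def total_length(self) -> int:
        return sum(self.lengths.values())


def default_build() -> GenomeBuild:
    """Human-like build: 22 autosomes with lengths and centromeres."""
    mb = 1_000_000
    lengths = {c: int(round(l * mb)) for c, (l, _, _) in _HUMAN_AUTOSOMES_MB.items()}
    cens = {
        c: (int(round(cs * mb)), int(round(ce * mb)))
        for c, (_, cs, ce) in _HUMAN_AUTOSOMES_MB.items()
    }
    return GenomeBuild(name="human-autosomes", lengths=lengths, centromeres=cens)


def compact_build(
    n_chromosomes: int = 8,
    chrom_length_mb: float = 160.0,
    centromere_mb: float = 3.0,
) -> GenomeBuild:
    """Small metacentric build for simulation studies and tests.

    Each chromosome has the centromere at its midpoint, so every arm is
    (chrom_length - centromere) / 2 long.
    """
    mb = 1_000_000
    length = int(round(chrom_length_mb * mb))
    half_cen = int(round(centromere_mb * mb / 2))
    mid = length // 2
    lengths = {f"c{i + 1}": length for i in range(n_chromosomes)}
    cens = {f"c{i + 1}": (mid - half_cen, mid + half_cen) for i in range(n_chromosomes)}
    return GenomeBuild(name=f"compact-{n_chromosomes}", lengths=lengths, centromeres=cens)
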