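"""Reference karyotype: chromosome sizes, centromeres, and named loci.

A simplified hg19-like female karyotype (22 autosomes + X, Y excluded) is
bundled as the default reference.  Centromere positions are single midpoints
(approximate band midpoints), sufficient for pericentric copy-number windows
and chromosome-arm bookkeeping; they are not base-exact assembly gaps.

All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "Chromosome",
    "Karyotype",
    "default_female_karyotype",
    "DEFAULT_LOCI",
    "ATM_LOCUS",
    "HALLMARK_LOSS_LOCI",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int  # midpoint, bp

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"chromosome {self.name}: centromere must lie strictly inside (0, length)"
            )


@dataclass(frozen=True)
class Karyotype:
    """Ordered set of chromosomes with centromere midpoints."""

    chromosomes: tuple[Chromosome, ...]
    sex: str = "female"

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def arm_of(self, chrom: str, pos: int) -> str:
        """Return 'p' or 'q' for a position on a chromosome."""
        c = self[chrom]
        if not 0 <= pos < c.length:
            raise ValueError(f"position {pos} outside {chrom} (length {c.length})")
        return "p" if pos < c.centromere else "q"

    def pericentric_window(self, chrom: str, half_width: int) -> tuple[int, int]:
        """Window [centromere - w, centromere + w) clipped to the chromosome."""
        c = self[chrom]
        return max(0, c.centromere - half_width), min(c.length, c.centromere + half_width)

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= start < end <= self[chrom].length:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )

    def to_yaml(self, path) -> None:
        data = {
            "sex": self.sex,
            "chromosomes": [
                {"name": c.name, "length": c.length, "centromere": c.centromere}
                for c in self.chromosomes
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Karyotype":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not data or "chromosomes" not in data:
            raise ValueError(f"karyotype file {path} missing 'chromosomes'")
        chroms = tuple(
            Chromosome(d["name"], int(d["length"]), int(d["centromere"]))
            for d in data["chromosomes"]
        )
        return cls(chromosomes=chroms, sex=data.get("sex", "female"))


# hg19-like sizes (bp) and approximate centromere midpoints (bp).
_HG19_FEMALE: tuple[tuple[str, int, int], ...] = (
    ("chr1", 249_250_621, 125_000_000),
    ("chr2", 243_199_373, 93_300_000),
    ("chr3", 198_022_430, 91_000_000),
    ("chr4", 191_154_276, 50_400_000),
    ("chr5", 180_915_260, 48_400_000),
    ("chr6", 171_115_067, 61_000_000),
    ("chr7", 159_138_663, 59_900_000),
    ("chr8", 146_364_022, 45_600_000),
    ("chr9", 141_213_431, 49_000_000),
    ("chr10", 135_534_747, 40_200_000),
    ("chr11", 135_006_516, 53_700_000),
    ("chr12", 133_851_895, 35_800_000),
    ("chr13", 115_169_878, 17_900_000),
    ("chr14", 107_349_540, 17_600_000),
    ("chr15", 102_531_392, 19_000_000),
    ("chr16", 90_354_753, 36_600_000),
    ("chr17", 81_195_210, 24_000_000),
    ("chr18", 78_077_248, 17_200_000),
    ("chr19", 59_128_983, 26_500_000),
    ("chr20", 63_025_520, 27_500_000),
    ("chr21", 48_129_895, 13_200_000),
    ("chr22", 51_304_566, 14_700_000),
    ("chrX", 155_270_560, 60_600_000),
)


def default_female_karyotype() -> Karyotype:
    """Simplified hg19-like female karyotype (22 autosomes + X)."""
    return Karyotype(
        chromosomes=tuple(Chromosome(*row) for row in _HG19_FEMALE), sex="female"
    )


# Named loci (approximate hg19 cytogenetic-band coordinates, 0-based half-open).
# The ATM locus band and the four recurrent-loss hallmark loci used throughout
# the cohort analyses.
ATM_LOCUS: tuple[str, int, int] = ("chr11", 106_600_000, 110_600_000)  # 11q22.3

HALLMARK_LOSS_LOCI: dict[str, tuple[str, int, int]] = {
    "13q14.11-q14.3": ("chr13", 40_800_000, 50_400_000),  # 9.6 Mb, contains RB1
    "17p13.2-p12": ("chr17", 3_300_000, 16_000_000),  # 12.7 Mb, contains MAP2K4
    "21p11.2-p11.1": ("chr21", 10_900_000, 12_100_000),  # 1.2 Mb, contains TPTE
    "22q11.23": ("chr22", 23_500_000, 25_500_000),  # 2.0 Mb, contains GSTT1
}

DEFAULT_LOCI: dict[str, tuple[str, int, int]] = {
    "ATM-11q22.3": ATM_LOCUS,
    **HALLMARK_LOSS_LOCI,
}
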