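"""Genetic sex inference from length-normalized chromosome read counts.

With a female reference genome (no Y chromosome available), sex is inferred
from the ratio of X-chromosome to autosome read density: a male carries one X
against two autosomal copies, so the length-normalized ChrX:autosome ratio is
expected near 0.5; a female's near 1. The comparison autosome should be of
similar size to X (Chr3 in the horse). Classification uses configurable,
disjoint ratio bands with an undetermined fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: Default classification bands around the expected ratios 0.5 (male) and
#: 1.0 (female); symmetric and non-overlapping, fully configurable.
MALE_BAND = (0.35, 0.65)
FEMALE_BAND = (0.8, 1.2)


@dataclass(frozen=True)
class ChromCounts:
    """Mapped-read count and length of one chromosome (one idxstats row)."""

    name: str
    mapped_reads: int
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if self.mapped_reads < 0:
            raise ValueError(f"chromosome {self.name}: mapped_reads must be >= 0")

    @property
    def density(self) -> float:
        """Mapped reads per base pair."""
        return self.mapped_reads / self.length


@dataclass(frozen=True)
class SexResult:
    """Outcome of the read-ratio sex test, with inputs echoed."""

    ratio: Optional[float]
    classification: str  # "male" | "female" | "undetermined"
    reason: str
    x: ChromCounts
    autosome: ChromCounts

    def to_dict(self) -> dict:
        return {
            "x_name": self.x.name,
            "x_mapped": self.x.mapped_reads,
            "x_length": self.x.length,
            "autosome_name": self.autosome.name,
            "autosome_mapped": self.autosome.mapped_reads,
            "autosome_length": self.autosome.length,
            "ratio": self.ratio,
            "classification": self.classification,
            "reason": self.reason,
        }


def read_idxstats(path) -> dict[str, ChromCounts]:
    """Parse a samtools-idxstats-style TSV (name, length, mapped, unmapped).

    Header/comment lines (non-numeric length or mapped fields) and the ``*``
    unplaced-read sentinel row are skipped; an empty or header-only file
    yields an empty mapping.
    """
    counts: dict[str, ChromCounts] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0] == "*" or parts[0].startswith("#"):
                continue
            try:
                length, mapped = int(parts[1]), int(parts[2])
            except ValueError:
                continue  # header or malformed row
            counts[parts[0]] = ChromCounts(parts[0], mapped, length)
    return counts


def infer_sex(
    x: ChromCounts,
    autosome: ChromCounts,
    male_band: tuple[float, float] = MALE_BAND,
    female_band: tuple[float, float] = FEMALE_BAND,
    min_reads: int = 100,
) -> SexResult:
    """Classify sex from the length-normalized X:autosome read-density ratio.

    ``ratio = (x.mapped/x.length) / (autosome.mapped/autosome.length)``;
    classification is band membership (inclusive bounds), undetermined when
    the ratio falls outside both bands or total reads are below ``min_reads``
    (guards against shallow-screening noise). Zero autosomal reads yield an
    undetermined result with an explicit reason rather than a division error.
    """
    if male_band[0] > male_band[1] or female_band[0] > female_band[1]:
        raise ValueError("classification bands must be (low, high) with low <= high")
    if not (male_band[1] < female_band[0] or female_band[1] < male_band[0]):
        raise ValueError("male and female bands must be disjoint")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")

    if autosome.mapped_reads == 0:
        return SexResult(None, "undetermined", "no mapped autosomal reads", x, autosome)
    ratio = x.density / autosome.density
    total = x.mapped_reads + autosome.mapped_reads
    if total < min_reads:
        return SexResult(
            ratio, "undetermined", f"only {total} reads (< min_reads={min_reads})", x, autosome
        )
    if male_band[0] <= ratio <= male_band[1]:
        return SexResult(ratio, "male", f"ratio {ratio:.3f} in male band {male_band}", x, autosome)
    if female_band[0] <= ratio <= female_band[1]:
        return SexResult(
            ratio, "female", f"ratio {ratio:.3f} in female band {female_band}", x, autosome
        )
    return SexResult(ratio, "undetermined", f"ratio {ratio:.3f} outside both bands", x, autosome)
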