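"""Genomic interval primitives shared across the package.

All internal coordinates are 0-based half-open on a named sequence;
conversions to 1-based inclusive (GFF3) or 0-based half-open (BED,
bedGraph) happen only in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A strand-aware genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start, end : int
        0-based half-open bounds, ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicWindow") -> bool:
        """True when the two intervals share >= 1 base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicWindow") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def key(self) -> str:
        """Compact ``chrom:start-end:strand`` identifier used in exports."""
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_region(cls, region: str, strand: str = "+") -> "GenomicWindow":
        """Parse a samtools-style ``chrom:start-end`` region string (0-based)."""
        chrom, _, span = region.rpartition(":")
        if not chrom:
            raise ValueError(f"cannot parse region {region!r}")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo), int(hi), strand)
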