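"""Benchmark metrics: label-based TPR and blank-experiment FPR.

A label is a genomic interval where a DER is expected (e.g. a validated
transcript portion).  The error E counts labels not overlapped by at
least one called DER, giving TPR = (N - E) / N.  In a blank experiment
(same-condition replicates split into two artificial groups) every called
DER is a false positive and FPR = #DERs / #segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .windows import GenomicWindow


@dataclass
class BenchmarkResult:
    n_labels: int
    n_missed: int
    tpr: float
    n_segments: int
    n_ders: int
    fpr: float


def tpr(
    labels: Sequence[GenomicWindow],
    ders: Sequence[GenomicWindow],
    ignore_strand: bool = False,
) -> float:
    """(N - E) / N where E = labels not overlapped (>=1 base) by any DER.

    Overlap is strand-aware by default since labels are strand-specific
    transcript portions.
    """
    if not labels:
        raise ValueError("label set must be non-empty")
    missed = 0
    for lab in labels:
        hit = any(
            lab.overlaps(d) and (ignore_strand or d.strand == lab.strand)
            for d in ders
        )
        missed += not hit
    return (len(labels) - missed) / len(labels)


def fpr(n_ders: int, n_segments: int) -> float:
    """#DERs / #segments for a blank design."""
    if n_segments < 1:
        raise ValueError("need >= 1 segment")
    if not 0 <= n_ders <= n_segments:
        raise ValueError("n_ders must lie in [0, n_segments]")
    return n_ders / n_segments


def benchmark(
    labels: Sequence[GenomicWindow],
    ders: Sequence[GenomicWindow],
    n_segments: int,
    ignore_strand: bool = False,
) -> BenchmarkResult:
    rate = tpr(labels, ders, ignore_strand)
    missed = round(len(labels) * (1.0 - rate))
    return BenchmarkResult(
        n_labels=len(labels),
        n_missed=missed,
        tpr=rate,
        n_segments=n_segments,
        n_ders=len(ders),
        fpr=fpr(len(ders), n_segments),
    )


def der_boundary_errors(
    labels: Sequence[GenomicWindow],
    ders: Sequence[GenomicWindow],
) -> list[tuple[float, float]]:
    """Boundary recovery error per label, in bases.

    For each label, the union span of same-strand DERs overlapping it is
    compared to the label: returns (|start error|, |end error|) pairs, or
    (inf, inf) when no DER overlaps the label.
    """
    out = []
    for lab in labels:
        hits = [d for d in ders if lab.overlaps(d) and d.strand == lab.strand]
        if not hits:
            out.append((float("inf"), float("inf")))
            continue
        lo = min(d.start for d in hits)
        hi = max(d.end for d in hits)
        out.append((abs(lo - lab.start), abs(hi - lab.end)))
    return out


def read_labels_bed(path) -> list[GenomicWindow]:
    """Load labels from BED6 (0-based half-open, strand in column 6)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicWindow(f[0], int(f[1]), int(f[2]), f[5]))
    return out
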