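"""Assign mapped reads to segments: the segments x samples count matrix.

A retained alignment unit (read or fragment, mirroring the profiles
module) is counted on every same-strand segment it overlaps by at least
one base, so a unit spanning m segment boundaries contributes to m + 1
rows.  Counts are raw; normalization happens in the DEA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import ReadUnit, read_units
from .windows import GenomicWindow


@dataclass
class CountMatrix:
    """Raw read counts, one row per segment and one column per sample."""

    segments: list[GenomicWindow]
    samples: list[tuple[str, str, int]]  # (sample_id, condition, replicate)
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.segments), len(self.samples)):
            raise ValueError("count matrix shape must be (n_segments, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[s.key for s in self.segments],
            columns=[s[0] for s in self.samples],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="segment")


def unit_arrays(units: Sequence[ReadUnit]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack units into (starts, ends, plus_strand_mask) arrays."""
    n = len(units)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    plus = np.empty(n, dtype=bool)
    for i, u in enumerate(units):
        starts[i] = u.start
        ends[i] = u.end
        plus[i] = u.strand == "+"
    return starts, ends, plus


def count_units_in_segments(
    units: Sequence[ReadUnit],
    segments: Sequence[GenomicWindow],
    multi_overlap: bool = True,
    _arrays: tuple | None = None,
) -> np.ndarray:
    """Count units on each segment's strand overlapping it by >= 1 base.

    With ``multi_overlap=False`` each unit is assigned only to the segment
    with the largest overlap (earliest segment on ties).  Sorted
    non-overlapping segments (the segmentation always tiles the window)
    take a vectorized path; arbitrary segment sets fall back to a scan.
    """
    counts = np.zeros(len(segments), dtype=np.int64)
    u_start, u_end, u_plus = unit_arrays(units) if _arrays is None else _arrays
    by_strand: dict[str, list[tuple[int, int, int]]] = {}
    for idx, seg in enumerate(segments):
        by_strand.setdefault(seg.strand, []).append((seg.start, seg.end, idx))
    for strand, segs in by_strand.items():
        segs.sort()
        seg_start = np.asarray([s[0] for s in segs])
        seg_end = np.asarray([s[1] for s in segs])
        seg_idx = np.asarray([s[2] for s in segs])
        mask = u_plus if strand == "+" else ~u_plus
        us, ue = u_start[mask], u_end[mask]
        tiled = np.all(seg_start[1:] >= seg_end[:-1]) if len(segs) > 1 else True
        if multi_overlap and tiled:
            # overlapped segment range per unit via binary search
            first = np.searchsorted(seg_end, us, side="right")
            last = np.searchsorted(seg_start, ue, side="left") - 1
            ok = first <= last
            first, last = first[ok], last[ok]
            diff = np.zeros(len(segs) + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            counts[seg_idx] += np.cumsum(diff[:-1])
            continue
        for s, e in zip(us, ue):
            k = int(np.searchsorted(seg_start, e, side="left"))
            hits = [
                (min(seg_end[i], e) - max(seg_start[i], s), seg_idx[i])
                for i in range(k)
                if min(seg_end[i], e) - max(seg_start[i], s) > 0
            ]
            if not hits:
                continue
            if multi_overlap:
                for _, idx in hits:
                    counts[idx] += 1
            else:
                best = max(hits, key=lambda h: (h[0], -h[1]))
                counts[best[1]] += 1
    return counts


def count_reads_in_segments(
    bam_paths: Sequence,
    samples: Sequence[tuple[str, str, int]],
    segments: Sequence[GenomicWindow],
    window: GenomicWindow,
    library_protocol: str = "fr",
    pairing_mode: str = "fragment",
    multi_overlap: bool = True,
    drop_duplicates: bool = False,
) -> CountMatrix:
    """Build the count matrix from one BAM per sample over the window."""
    if len(bam_paths) != len(samples):
        raise ValueError("need one BAM path per sample")
    mat = np.zeros((len(segments), len(samples)), dtype=np.int64)
    for j, path in enumerate(bam_paths):
        units = read_units(
            path, window, library_protocol, pairing_mode, drop_duplicates
        )
        mat[:, j] = count_units_in_segments(units, segments, multi_overlap)
    return CountMatrix(list(segments), list(samples), mat)
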