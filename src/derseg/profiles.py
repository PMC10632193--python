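"""Per-base coverage profiles and the differential transcription profile.

For each sample and strand a coverage profile ``Q`` is built from the BAM
file over a user-chosen window.  The default heuristic combines the 5' and
3' read-end profiles through a shifted geometric mean,

    Q[i] + 1 = sqrt((Q5[i] + 1) * (Q3[i] + 1)),

which responds to both transcript ends while damping isolated spikes of
either.  Alternatives (pure 5', pure 3', full-length coverage) are
selectable.  The two conditions are then contrasted per base as

    Y[i] = mean_r log2(Q[i, cond1, r] + 1) - mean_r log2(Q[i, cond2, r] + 1),

the per-base log2 fold change that downstream segmentation operates on.
Sequencing-depth differences shift Y by a constant offset only, which the
segmentation is invariant to, so Y is deliberately left un-normalized.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .windows import GenomicWindow

COVERAGE_MODES = ("five_prime", "three_prime", "full_length", "geometric")
LIBRARY_PROTOCOLS = ("fr", "rf", "unstranded")
PAIRING_MODES = ("fragment", "read")

#: default fetch padding so fragments anchored outside the window are seen
DEFAULT_MAX_FRAGMENT = 2000


@dataclass
class ReadUnit:
    """One retained alignment unit: a single-end read, one mate, or a fragment."""

    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # biological transcript strand after protocol resolution
    blocks: tuple = ()  # aligned blocks for spliced full-length coverage

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class CoverageProfile:
    """Per-base coverage of one sample on one strand of a window."""

    window: GenomicWindow
    sample_id: str
    condition: str
    replicate: int
    mode: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in COVERAGE_MODES:
            raise ValueError(f"unknown coverage mode {self.mode!r}")
        if self.values.shape != (len(self.window),):
            raise ValueError("values length must equal window length")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")


@dataclass
class DifferentialProfile:
    """Per-base log2 fold-change Y over one strand of a window."""

    window: GenomicWindow
    values: np.ndarray
    n_reps_cond1: int
    n_reps_cond2: int
    reference_condition: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.window),):
            raise ValueError("values length must equal window length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log2-FC profile must be finite everywhere")


def _open_indexed(bam_path) -> pysam.AlignmentFile:
    path = os.fspath(bam_path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"BAM file not found: {path}")
    af = pysam.AlignmentFile(path, "rb")
    if not af.has_index():
        af.close()
        raise FileNotFoundError(
            f"BAM index (.bai) missing for {path}; run 'samtools index' first"
        )
    return af


def _mate1_is_reverse(read: pysam.AlignedSegment) -> bool:
    # strand inference is anchored on mate 1 for paired layouts
    if not read.is_paired or read.is_read1:
        return read.is_reverse
    return not read.is_reverse


def _unit_strand(read: pysam.AlignedSegment, library_protocol: str) -> str:
    if library_protocol == "unstranded":
        return "+"
    rev = _mate1_is_reverse(read)
    if library_protocol == "rf":
        rev = not rev
    return "-" if rev else "+"


def _keep(read: pysam.AlignedSegment, drop_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
        return False
    if drop_duplicates and read.is_duplicate:
        return False
    return True


def read_units(
    bam_path,
    window: GenomicWindow,
    library_protocol: str = "fr",
    pairing_mode: str = "fragment",
    drop_duplicates: bool = False,
    max_fragment: int = DEFAULT_MAX_FRAGMENT,
) -> list[ReadUnit]:
    """Fetch retained alignment units whose projection overlaps the window.

    ``pairing_mode="fragment"`` collapses each properly-paired pair into a
    single unit spanning the outermost template ends (counted once, via the
    leftmost mate); ``"read"`` keeps mates as independent units.  Units on
    both strands are returned; callers filter by strand as needed.
    """
    if library_protocol not in LIBRARY_PROTOCOLS:
        raise ValueError(f"unknown library protocol {library_protocol!r}")
    if pairing_mode not in PAIRING_MODES:
        raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    if library_protocol == "unstranded":
        warnings.warn(
            "unstranded protocol: all reads assigned to the '+' profile",
            stacklevel=2,
        )
    units: list[ReadUnit] = []
    with _open_indexed(bam_path) as af:
        if window.chrom not in af.references:
            raise ValueError(
                f"sequence {window.chrom!r} absent from BAM header of {bam_path}"
            )
        pad = max_fragment if pairing_mode == "fragment" else 0
        fetch_start = max(0, window.start - pad)
        fetch_end = min(af.get_reference_length(window.chrom), window.end + pad)
        for read in af.fetch(window.chrom, fetch_start, fetch_end):
            if not _keep(read, drop_duplicates):
                continue
            strand = _unit_strand(read, library_protocol)
            if pairing_mode == "fragment" and read.is_proper_pair:
                # one unit per pair, anchored on the leftmost mate
                if read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
                blocks = ((start, end),)
            else:
                start = read.reference_start
                end = read.reference_end
                blocks = tuple(read.get_blocks())
            if start < window.end and end > window.start:
                units.append(ReadUnit(start, end, strand, blocks))
    return units


def extract_read_ends(
    bam_path,
    window: GenomicWindow,
    library_protocol: str = "fr",
    pairing_mode: str = "fragment",
    drop_duplicates: bool = False,
) -> list[tuple[int, int, str]]:
    """Return ``(five_prime_pos, three_prime_pos, strand)`` per retained unit.

    Positions are 0-based genome coordinates; an empty region yields an
    empty list.  A missing index or unknown sequence name raises.
    """
    return [
        (u.five_prime, u.three_prime, u.strand)
        for u in read_units(
            bam_path, window, library_protocol, pairing_mode, drop_duplicates
        )
    ]


def end_coverage(
    read_ends: Iterable[tuple[int, int, str]],
    window: GenomicWindow,
    which_end: str,
) -> np.ndarray:
    """Count reads on ``window.strand`` whose chosen end falls on each base."""
    if which_end not in ("five_prime", "three_prime"):
        raise ValueError(f"which_end must be five_prime/three_prime, got {which_end!r}")
    n = len(window)
    sel = 0 if which_end == "five_prime" else 1
    pos = np.fromiter(
        (e[sel] for e in read_ends if e[2] == window.strand),
        dtype=np.int64,
    )
    pos = pos[(pos >= window.start) & (pos < window.end)] - window.start
    return np.bincount(pos, minlength=n).astype(np.int64)


def full_length_coverage(
    read_intervals: Iterable[tuple[int, int]],
    window: GenomicWindow,
) -> np.ndarray:
    """Depth of half-open read intervals over the window (difference-array sum)."""
    n = len(window)
    diff = np.zeros(n + 1, dtype=np.int64)
    for s, e in read_intervals:
        if e <= s:
            raise ValueError(f"invalid interval [{s}, {e})")
        lo = max(s, window.start) - window.start
        hi = min(e, window.end) - window.start
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    return np.cumsum(diff[:-1])


def geometric_coverage(q5: np.ndarray, q3: np.ndarray) -> np.ndarray:
    """Shifted geometric mean of the 5' and 3' end profiles.

    ``out[i] = sqrt((q5[i]+1) * (q3[i]+1)) - 1``; equals ``q`` exactly when
    both inputs equal ``q``.
    """
    q5 = np.asarray(q5, dtype=float)
    q3 = np.asarray(q3, dtype=float)
    if q5.shape != q3.shape:
        raise ValueError("5' and 3' profiles must have equal length")
    if np.any(q5 < 0) or np.any(q3 < 0):
        raise ValueError("end counts must be >= 0")
    return np.sqrt((q5 + 1.0) * (q3 + 1.0)) - 1.0


def coverage_from_units(
    units: Sequence[ReadUnit],
    window: GenomicWindow,
    mode: str = "geometric",
) -> np.ndarray:
    """Build one per-base coverage vector from pre-fetched units."""
    if mode not in COVERAGE_MODES:
        raise ValueError(f"unknown coverage mode {mode!r}")
    ends = [(u.five_prime, u.three_prime, u.strand) for u in units]
    if mode == "five_prime":
        return end_coverage(ends, window, "five_prime").astype(float)
    if mode == "three_prime":
        return end_coverage(ends, window, "three_prime").astype(float)
    if mode == "full_length":
        blocks = [
            b for u in units if u.strand == window.strand for b in (u.blocks or ((u.start, u.end),))
        ]
        return full_length_coverage(blocks, window).astype(float)
    q5 = end_coverage(ends, window, "five_prime")
    q3 = end_coverage(ends, window, "three_prime")
    return geometric_coverage(q5, q3)


def coverage_profile(
    bam_path,
    window: GenomicWindow,
    sample_id: str,
    condition: str,
    replicate: int,
    mode: str = "geometric",
    library_protocol: str = "fr",
    pairing_mode: str = "fragment",
    drop_duplicates: bool = False,
) -> CoverageProfile:
    """Convenience wrapper: BAM -> CoverageProfile for one sample and strand."""
    units = read_units(bam_path, window, library_protocol, pairing_mode, drop_duplicates)
    values = coverage_from_units(units, window, mode)
    return CoverageProfile(window, sample_id, condition, replicate, mode, values)


def log2_fc_profile(
    cond1_profiles: Sequence[CoverageProfile],
    cond2_profiles: Sequence[CoverageProfile],
) -> DifferentialProfile:
    """Per-base log2-FC of condition 1 over condition 2 (the reference).

    ``Y[i] = mean_r log2(Q1[i,r]+1) - mean_r log2(Q2[i,r]+1)``.
    """
    if not cond1_profiles or not cond2_profiles:
        raise ValueError("need >= 1 coverage profile per condition")
    ref = cond1_profiles[0]
    for p in (*cond1_profiles, *cond2_profiles):
        if p.window != ref.window or p.mode != ref.mode:
            raise ValueError("all profiles must share window, strand and mode")
    for group in (cond1_profiles, cond2_profiles):
        conds = {p.condition for p in group}
        if len(conds) != 1:
            raise ValueError(f"inconsistent condition labels within a group: {conds}")
    m1 = np.mean([np.log2(p.values + 1.0) for p in cond1_profiles], axis=0)
    m2 = np.mean([np.log2(p.values + 1.0) for p in cond2_profiles], axis=0)
    return DifferentialProfile(
        window=ref.window,
        values=m1 - m2,
        n_reps_cond1=len(cond1_profiles),
        n_reps_cond2=len(cond2_profiles),
        reference_condition=cond2_profiles[0].condition,
    )


def normalization_offset(
    size_factors_cond1: Sequence[float],
    size_factors_cond2: Sequence[float],
) -> float:
    """Offset rho between raw and depth-normalized per-base log2-FC.

    ``rho = mean(log2 s_1r) - mean(log2 s_2r)``.  Informational only: the
    changepoints of the segmentation are invariant to a constant shift of Y,
    so rho never enters the segmentation itself.
    """
    s1 = np.asarray(size_factors_cond1, dtype=float)
    s2 = np.asarray(size_factors_cond2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("size factors must be strictly positive")
    return float(np.mean(np.log2(s1)) - np.mean(np.log2(s2)))
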