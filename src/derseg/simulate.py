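"""Synthetic stranded RNA-seq with planted differential regions.

The generator emulates the statistical structure the pipeline assumes:
per-base 5'-end counts with a piecewise-constant baseline intensity, a
planted piecewise-constant log2-FC applied to condition 1, and negative
binomial replicate noise (variance mu + alpha * mu^2; Poisson when
alpha = 0).  Counts can be materialized as small sorted+indexed BAMs of
constant-length single-end reads whose 5'-end coverage reproduces the
simulated counts exactly (the 3'-end profile is the 5' profile shifted by
read_length - 1), so the full BAM-to-DER pipeline is exercised without
external data.

It does not model sequencing error, GC or positional bias, fragment-length
variation, or paired-end layouts.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .windows import GenomicWindow

CONDITION_1 = "treated"
CONDITION_2 = "control"


@dataclass
class SimulationScenario:
    """All knobs of one synthetic experiment; deterministic given ``seed``."""

    window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("synthS", 100, 10100, "+")
    )
    #: per-strand baseline 5'-end intensity: scalar or per-base array
    baseline: dict = field(default_factory=lambda: {"+": 10.0, "-": 4.0})
    #: planted DERs: (interval with strand, log2-FC applied to condition 1)
    planted_ders: list = field(default_factory=list)
    dispersion: float = 0.05
    reps_per_condition: tuple = (2, 2)
    #: one depth factor per sample, condition-1 replicates first
    sample_depth_factors: Optional[Sequence[float]] = None
    read_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for der, effect in self.planted_ders:
            if not self.window.contains(
                GenomicWindow(der.chrom, der.start, der.end, der.strand)
            ):
                raise ValueError(f"planted DER {der} outside the window")
            if not np.isfinite(effect):
                raise ValueError("planted effects must be finite")

    @property
    def n_samples(self) -> int:
        return sum(self.reps_per_condition)

    def depth_factors(self) -> np.ndarray:
        if self.sample_depth_factors is None:
            return np.ones(self.n_samples)
        f = np.asarray(self.sample_depth_factors, dtype=float)
        if f.shape != (self.n_samples,) or np.any(f <= 0):
            raise ValueError("need one positive depth factor per sample")
        return f

    def baseline_vector(self, strand: str) -> np.ndarray:
        base = self.baseline.get(strand, 0.0)
        n = len(self.window)
        vec = np.broadcast_to(np.asarray(base, dtype=float), (n,)).copy()
        if np.any(vec < 0):
            raise ValueError("baseline intensity must be >= 0")
        return vec

    def effect_vector(self, strand: str) -> np.ndarray:
        """Planted per-base log2-FC (condition 1 relative to condition 2)."""
        eff = np.zeros(len(self.window))
        for der, effect in self.planted_ders:
            if der.strand == strand:
                lo = der.start - self.window.start
                hi = der.end - self.window.start
                eff[lo:hi] += effect
        return eff

    def labels(self) -> list[GenomicWindow]:
        """Strand-aware intervals expected to contain a DER."""
        return [
            GenomicWindow(d.chrom, d.start, d.end, d.strand)
            for d, _ in self.planted_ders
        ]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if alpha == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / alpha
        out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def simulate_counts(
    scenario: SimulationScenario, condition: int
) -> dict[str, list[np.ndarray]]:
    """Per-strand, per-replicate 5'-end count vectors for one condition.

    Replicate r of condition c has per-base mean
    ``depth_factor * baseline * 2**(effect * [c == 1])``.
    """
    if condition not in (1, 2):
        raise ValueError("condition must be 1 or 2")
    reps = scenario.reps_per_condition[condition - 1]
    depth = scenario.depth_factors()
    offset = 0 if condition == 1 else scenario.reps_per_condition[0]
    out: dict[str, list[np.ndarray]] = {}
    for strand in ("+", "-"):
        base = scenario.baseline_vector(strand)
        if condition == 1:
            base = base * np.exp2(scenario.effect_vector(strand))
        vecs = []
        for r in range(reps):
            rng = np.random.default_rng(
                [scenario.seed, condition, r, 0 if strand == "+" else 1]
            )
            vecs.append(_nb_draw(rng, depth[offset + r] * base, scenario.dispersion))
        out[strand] = vecs
    return out


def write_synthetic_bam(
    counts_by_strand: dict[str, np.ndarray],
    scenario: SimulationScenario,
    out_path,
    write_reference: bool = False,
):
    """Materialize 5'-end count vectors as a sorted, indexed BAM.

    Each count of c at window base i becomes c constant-length reads whose
    5' end sits at i on the requested strand; minus-strand reads extend
    leftward, so both end profiles are fully controlled.
    """
    w = scenario.window
    L = scenario.read_length
    ref_len = w.end + L + 10
    reads: list[tuple[int, bool, int]] = []
    for strand, counts in counts_by_strand.items():
        counts = np.asarray(counts)
        if counts.shape != (len(w),):
            raise ValueError("count vector length must equal window length")
        for off in np.flatnonzero(counts):
            pos = w.start + int(off)
            start = pos if strand == "+" else pos - L + 1
            if start < 0 or start + L > ref_len:
                raise ValueError(
                    f"read at {pos} ({strand}) falls outside the reference"
                )
            reads.append((start, strand == "-", int(counts[off])))
    reads.sort()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": w.chrom, "LN": ref_len}],
    }
    out_path = os.fspath(out_path)
    with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
        serial = 0
        for start, is_reverse, copies in reads:
            for _ in range(copies):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"synth_{serial}"
                serial += 1
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_sequence = "A" * L
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                a.flag = 16 if is_reverse else 0
                bam.write(a)
    pysam.index(out_path)
    if write_reference:
        fa = os.path.splitext(out_path)[0] + ".fa"
        with open(fa, "w") as fh:
            fh.write(f">{w.chrom}\n")
            seq = "A" * ref_len
            for i in range(0, ref_len, 70):
                fh.write(seq[i : i + 70] + "\n")
    return out_path


def simulate_bams(
    scenario: SimulationScenario, out_dir
) -> "pandas.DataFrame":  # noqa: F821
    """One BAM per replicate of both conditions plus a TSV sample sheet."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for condition in (1, 2):
        counts = simulate_counts(scenario, condition)
        label = CONDITION_1 if condition == 1 else CONDITION_2
        for r in range(scenario.reps_per_condition[condition - 1]):
            path = os.path.join(out_dir, f"{label}_rep{r + 1}.bam")
            write_synthetic_bam(
                {s: counts[s][r] for s in counts}, scenario, path
            )
            rows.append(
                {
                    "sample": f"{label}_rep{r + 1}",
                    "condition": label,
                    "replicate": r + 1,
                    # relative to the sample sheet's own directory
                    "bam": os.path.basename(path),
                }
            )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    return sheet


def three_der_scenario(seed: int = 0) -> SimulationScenario:
    """Reference recovery scenario: 10 kb window, three planted DERs.

    Effects +1, -1 (forward strand) and +2 (reverse strand), 2 vs 2
    replicates, NB dispersion 0.05, short (10 nt) reads so that the
    read-length smear of the 3'-end profile stays well inside a +-10 base
    boundary tolerance.
    """
    w = GenomicWindow("synthS", 100, 10100, "+")
    return SimulationScenario(
        window=w,
        baseline={"+": 10.0, "-": 4.0},
        planted_ders=[
            (GenomicWindow("synthS", 2000, 2600, "+"), 1.0),
            (GenomicWindow("synthS", 5000, 5700, "+"), -1.0),
            (GenomicWindow("synthS", 8000, 8400, "-"), 2.0),
        ],
        dispersion=0.05,
        reps_per_condition=(2, 2),
        read_length=10,
        seed=seed,
    )


def blank_scenario(seed: int = 0, n_reps: int = 10) -> SimulationScenario:
    """Blank-experiment scenario: same-condition replicates, no effect.

    5 kb window, flat baselines on both strands, NB dispersion 0.05; all
    replicates are simulated as condition 1 and later resampled into
    artificial two-group designs.
    """
    return SimulationScenario(
        window=GenomicWindow("synthS", 100, 5100, "+"),
        baseline={"+": 5.0, "-": 2.0},
        dispersion=0.05,
        reps_per_condition=(n_reps, 0),
        read_length=10,
        seed=seed,
    )


def blank_resample(
    replicate_ids: Sequence,
    group_size: int,
    seed: int = 0,
    max_designs: Optional[int] = None,
) -> list[tuple[tuple, tuple]]:
    """Distinct unordered splits of same-condition replicates into two groups.

    Exhaustive enumeration of disjoint equal-size group pairs, optionally
    subsampled uniformly to ``max_designs``.  Every DER found between two
    such groups is a false positive by construction.
    """
    ids = list(replicate_ids)
    if group_size < 1 or 2 * group_size > len(ids):
        raise ValueError(
            f"group size {group_size} infeasible for {len(ids)} replicates"
        )
    seen = set()
    designs = []
    for a in itertools.combinations(ids, group_size):
        rest = [x for x in ids if x not in a]
        for b in itertools.combinations(rest, group_size):
            key = frozenset((frozenset(a), frozenset(b)))
            if key in seen:
                continue
            seen.add(key)
            designs.append((a, b))
    if max_designs is not None and len(designs) > max_designs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(designs), size=max_designs, replace=False)
        designs = [designs[i] for i in sorted(idx)]
    return designs
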