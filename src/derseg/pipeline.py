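"""End-to-end orchestration: BAMs -> profiles -> segmentation -> DEA -> export.

The four stages mirror the method: (1) per-strand coverage and per-base
log2-FC profiles, (2) FPOP segmentation of each strand plus read-to-segment
counting, (3) NB Wald differential testing with BH adjustment and a
post-hoc FDP bound over the pooled two-strand segment family, (4) optional
nearest-annotation labeling and genome-browser export.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_nearest, labels_frame, read_annotations
from .counting import CountMatrix, count_units_in_segments
from .dea import DERCall, call_ders, run_dea
from .io_export import ExportBundle, write_tracks
from .profiles import (
    CoverageProfile,
    DifferentialProfile,
    coverage_from_units,
    log2_fc_profile,
    read_units,
)
from .segmentation import segment_profile
from .windows import GenomicWindow

logger = logging.getLogger("derseg")


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class PipelineConfig:
    sample_sheet: str
    region: str  # chrom:start-end, 0-based half-open
    reference_condition: str
    coverage_mode: str = "geometric"
    library_protocol: str = "fr"
    pairing_mode: str = "fragment"
    lam: float = 2.0
    fc_threshold: float = 1.5
    fdp_target: float = 0.05
    alpha: float = 0.05
    annotation: Optional[str] = None
    out_dir: str = "derseg_out"
    seed: int = 0
    log_level: str = "INFO"
    size_factor_fallback: str = "error"


@dataclass
class SampleData:
    """Cached alignment units for one sample over the analysis window."""

    sample_id: str
    condition: str
    replicate: int
    units: list
    _arrays: Optional[tuple] = None

    @property
    def unit_arrays(self) -> tuple:
        if self._arrays is None:
            from .counting import unit_arrays

            self._arrays = unit_arrays(self.units)
        return self._arrays


@dataclass
class PipelineResult:
    dea_table: pd.DataFrame
    der_call: DERCall
    segments: list
    count_matrix: CountMatrix
    profiles_by_strand: dict
    diff_by_strand: dict
    bundle: Optional[ExportBundle] = None

    @property
    def n_ders(self) -> int:
        return int(np.sum(self.der_call.selected))

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def der_windows(self) -> list[GenomicWindow]:
        rows = self.dea_table[self.der_call.selected]
        return [
            GenomicWindow(r.chrom, r.start, r.end, r.strand)
            for r in rows.itertuples()
        ]


def read_sample_sheet(path) -> pd.DataFrame:
    """TSV with header columns sample, condition, replicate, bam."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "replicate", "bam"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["condition"].nunique() != 2:
        raise ValueError("sample sheet must contain exactly two conditions")
    return sheet


def prepare_samples(
    sheet: pd.DataFrame,
    window: GenomicWindow,
    library_protocol: str = "fr",
    pairing_mode: str = "fragment",
    base_dir: Optional[str] = None,
) -> list[SampleData]:
    """Fetch and cache alignment units once per sample."""
    samples = []
    for row in sheet.itertuples():
        bam = row.bam
        if base_dir is not None and not os.path.isabs(bam):
            bam = os.path.join(base_dir, bam)
        try:
            units = read_units(bam, window, library_protocol, pairing_mode)
        except Exception as exc:
            raise PipelineError(f"profiles stage failed for {row.sample}: {exc}") from exc
        logger.info("sample %s: %d alignment units", row.sample, len(units))
        samples.append(SampleData(row.sample, row.condition, int(row.replicate), units))
    return samples


def analyze_samples(
    samples: Sequence[SampleData],
    window: GenomicWindow,
    reference_condition: str,
    coverage_mode: str = "geometric",
    lam: float = 2.0,
    fc_threshold: float = 1.5,
    fdp_target: float = 0.05,
    alpha: float = 0.05,
    size_factor_fallback: str = "poscounts",
    coverage_cache: Optional[dict] = None,
) -> PipelineResult:
    """Run profiles -> segmentation -> counting -> DEA on cached units.

    ``coverage_cache`` maps (sample_id, strand) -> coverage vector and lets
    repeated designs over the same samples (blank resampling) skip the
    coverage computation.
    """
    conditions = {s.condition for s in samples}
    if reference_condition not in conditions or len(conditions) != 2:
        raise PipelineError(
            f"dea stage: need two conditions including reference "
            f"{reference_condition!r}, got {sorted(conditions)}"
        )
    (other,) = conditions - {reference_condition}

    profiles_by_strand: dict[str, dict[str, list[CoverageProfile]]] = {}
    diff_by_strand: dict[str, DifferentialProfile] = {}
    all_segments: list[GenomicWindow] = []
    for strand in ("+", "-"):
        swin = GenomicWindow(window.chrom, window.start, window.end, strand)
        by_cond: dict[str, list[CoverageProfile]] = {other: [], reference_condition: []}
        for s in samples:
            key = (s.sample_id, strand)
            if coverage_cache is not None and key in coverage_cache:
                values = coverage_cache[key]
            else:
                values = coverage_from_units(s.units, swin, coverage_mode)
                if coverage_cache is not None:
                    coverage_cache[key] = values
            by_cond[s.condition].append(
                CoverageProfile(swin, s.sample_id, s.condition, s.replicate,
                                coverage_mode, values)
            )
        profiles_by_strand[strand] = by_cond
        diff = log2_fc_profile(by_cond[other], by_cond[reference_condition])
        diff_by_strand[strand] = diff
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, segments = segment_profile(diff, lam=lam)
        logger.info("strand %s: %d segments", strand, len(segments))
        all_segments.extend(segments)

    sample_meta = [(s.sample_id, s.condition, s.replicate) for s in samples]
    mat = np.zeros((len(all_segments), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mat[:, j] = count_units_in_segments(
            s.units, all_segments, _arrays=s.unit_arrays
        )
    count_matrix = CountMatrix(all_segments, sample_meta, mat)

    try:
        dea_table = run_dea(
            count_matrix, reference_condition, fallback=size_factor_fallback
        )
    except Exception as exc:
        raise PipelineError(f"dea stage failed: {exc}") from exc
    der_call = call_ders(dea_table, fc_threshold, fdp_target, alpha)
    dea_table = dea_table.copy()
    dea_table["der"] = der_call.selected
    dea_table.attrs["fdp_bound"] = der_call.fdp_bound
    logger.info(
        "%d/%d segments called DER (FDP bound %.3f)",
        int(der_call.selected.sum()), len(all_segments), der_call.fdp_bound,
    )
    return PipelineResult(
        dea_table=dea_table,
        der_call=der_call,
        segments=all_segments,
        count_matrix=count_matrix,
        profiles_by_strand=profiles_by_strand,
        diff_by_strand=diff_by_strand,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline from a config; writes the export bundle."""
    logging.basicConfig(level=config.log_level)
    window = GenomicWindow.from_region(config.region)
    sheet = read_sample_sheet(config.sample_sheet)
    samples = prepare_samples(
        sheet, window, config.library_protocol, config.pairing_mode,
        base_dir=os.path.dirname(os.path.abspath(config.sample_sheet)),
    )
    result = analyze_samples(
        samples,
        window,
        config.reference_condition,
        coverage_mode=config.coverage_mode,
        lam=config.lam,
        fc_threshold=config.fc_threshold,
        fdp_target=config.fdp_target,
        alpha=config.alpha,
        size_factor_fallback=config.size_factor_fallback,
    )
    if config.annotation:
        try:
            anns = read_annotations(config.annotation)
        except Exception as exc:
            raise PipelineError(f"annotation stage failed: {exc}") from exc
        ders = result.der_windows()
        labels = annotate_nearest(ders, anns)
        frame = labels_frame(labels)
        der_idx = np.flatnonzero(result.der_call.selected)
        result.dea_table["nearest_features"] = ""
        result.dea_table["labels"] = ""
        for pos, row in frame.iterrows():
            result.dea_table.loc[
                result.dea_table.index[der_idx[pos]],
                ["nearest_features", "labels"],
            ] = [row["nearest_features"], row["labels"]]
    os.makedirs(config.out_dir, exist_ok=True)
    try:
        bundle = write_tracks(
            result.dea_table,
            result.der_call.selected,
            result.profiles_by_strand,
            result.diff_by_strand,
            config.out_dir,
        )
    except Exception as exc:
        raise PipelineError(f"export stage failed: {exc}") from exc
    result.bundle = bundle
    result.dea_table.to_csv(
        os.path.join(config.out_dir, "dea.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    result.count_matrix.to_tsv(os.path.join(config.out_dir, "counts.tsv"))
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def run_blank_designs(
    samples: Sequence[SampleData],
    window: GenomicWindow,
    designs: Sequence[tuple],
    coverage_mode: str = "geometric",
    lam: float = 2.0,
    fc_threshold: float = 1.5,
    fdp_target: float = 0.05,
    alpha: float = 0.05,
) -> list[tuple[int, int, float]]:
    """FPR of each artificial two-group design over same-condition samples.

    Returns ``(n_ders, n_segments, fpr)`` per design; all DERs are false
    positives by construction.
    """
    by_id = {s.sample_id: s for s in samples}
    cache: dict = {}
    out = []
    for group_a, group_b in designs:
        relabeled = [
            SampleData(sid, "groupA", i + 1, by_id[sid].units,
                       by_id[sid].unit_arrays)
            for i, sid in enumerate(group_a)
        ] + [
            SampleData(sid, "groupB", i + 1, by_id[sid].units,
                       by_id[sid].unit_arrays)
            for i, sid in enumerate(group_b)
        ]
        res = analyze_samples(
            relabeled, window, "groupB",
            coverage_mode=coverage_mode, lam=lam,
            fc_threshold=fc_threshold, fdp_target=fdp_target, alpha=alpha,
            size_factor_fallback="poscounts", coverage_cache=cache,
        )
        out.append((res.n_ders, res.n_segments, res.n_ders / res.n_segments))
    return out
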