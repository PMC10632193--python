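"""Genome-browser exports: BED6, GFF3, bedGraph, and an IGV session.

Internal coordinates are 0-based half-open; BED and bedGraph keep that
convention while GFF3 is written 1-based inclusive.  All writers take an
explicit float precision so exports are byte-stable across runs.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .windows import GenomicWindow

#: track colors, RGB strings as IGV expects them
COLOR_UP = "0,158,115"
COLOR_DOWN = "134,46,156"
COLOR_NEUTRAL = "153,153,153"


@dataclass
class ExportBundle:
    """File paths produced by one export run."""

    der_gff3: str
    not_der_gff3: str
    segmentation_gff3: str
    segmentation_bed: str
    coverage_bedgraphs: list[str] = field(default_factory=list)
    log2fc_bedgraphs: list[str] = field(default_factory=list)
    session_xml: Optional[str] = None

    def all_files(self) -> list[str]:
        files = [
            self.der_gff3,
            self.not_der_gff3,
            self.segmentation_gff3,
            self.segmentation_bed,
            *self.coverage_bedgraphs,
            *self.log2fc_bedgraphs,
        ]
        if self.session_xml:
            files.append(self.session_xml)
        return files


def write_bed(
    segments: Sequence[GenomicWindow],
    path,
    scores: Optional[Sequence[float]] = None,
    names: Optional[Sequence[str]] = None,
    precision: int = 6,
) -> None:
    """BED6: 0-based half-open, score column carries the per-segment value."""
    with open(path, "w", newline="\n") as fh:
        for i, seg in enumerate(segments):
            score = 0.0 if scores is None else float(scores[i])
            name = names[i] if names is not None else f"segment_{i + 1}"
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\t"
                f"{score:.{precision}g}\t{seg.strand}\n"
            )


def read_bed(path) -> tuple[list[GenomicWindow], list[float], list[str]]:
    segments, scores, names = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            segments.append(GenomicWindow(f[0], int(f[1]), int(f[2]), f[5]))
            names.append(f[3])
            scores.append(float(f[4]))
    return segments, scores, names


def write_gff3(
    segments: Sequence[GenomicWindow],
    path,
    source: str = "derseg",
    feature_type: str = "region",
    attributes: Optional[Sequence[dict]] = None,
    scores: Optional[Sequence[float]] = None,
    precision: int = 6,
) -> None:
    """GFF3 with 1-based inclusive coordinates and color attributes."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for i, seg in enumerate(segments):
            score = "." if scores is None else f"{float(scores[i]):.{precision}g}"
            attrs = dict(attributes[i]) if attributes is not None else {}
            attrs.setdefault("ID", f"{feature_type}_{i + 1}")
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seg.chrom}\t{source}\t{feature_type}\t{seg.start + 1}\t{seg.end}\t"
                f"{score}\t{seg.strand}\t.\t{attr_str}\n"
            )


def read_gff3(path) -> tuple[list[GenomicWindow], list[dict]]:
    """Minimal reader for round-trip checks of this package's own GFF3."""
    segments, attributes = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            segments.append(GenomicWindow(f[0], int(f[3]) - 1, int(f[4]), f[6]))
            attributes.append(
                dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            )
    return segments, attributes


def write_bedgraph(
    chrom: str,
    start: int,
    values: np.ndarray,
    path,
    track_name: Optional[str] = None,
    precision: int = 6,
) -> None:
    """Per-base values run-length collapsed into bedGraph intervals."""
    values = np.asarray(values, dtype=float)
    with open(path, "w", newline="\n") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        if values.size == 0:
            return
        # run-length encode equal consecutive values
        change = np.flatnonzero(np.diff(values)) + 1
        bounds = np.concatenate(([0], change, [values.size]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            fh.write(
                f"{chrom}\t{start + lo}\t{start + hi}\t{values[lo]:.{precision}g}\n"
            )


def read_bedgraph(path) -> tuple[str, int, np.ndarray]:
    """Expand a bedGraph back to per-base values (single contiguous block)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    if not rows:
        raise ValueError(f"empty bedGraph: {path}")
    chrom, start = rows[0][0], rows[0][1]
    n = rows[-1][2] - start
    values = np.empty(n)
    for _, lo, hi, v in rows:
        values[lo - start : hi - start] = v
    return chrom, start, values


def write_igv_session(
    track_files: Sequence[str],
    path,
    genome: str = "synthetic",
    locus: Optional[str] = None,
) -> None:
    """IGV 2.x session XML referencing each track with a relative path."""
    base = os.path.dirname(os.path.abspath(path))
    session = ET.Element("Session", genome=genome, version="8")
    if locus:
        session.set("locus", locus)
    resources = ET.SubElement(session, "Resources")
    panel = ET.SubElement(session, "Panel", name="DataPanel")
    for track in track_files:
        rel = os.path.relpath(os.path.abspath(track), base)
        ET.SubElement(resources, "Resource", path=rel)
        ET.SubElement(panel, "Track", id=rel, name=os.path.basename(track))
    tree = ET.ElementTree(session)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def write_tracks(
    dea_table: pd.DataFrame,
    der_selected: np.ndarray,
    profiles_by_strand: dict,
    diff_by_strand: dict,
    out_dir,
    genome: str = "synthetic",
    precision: int = 6,
) -> ExportBundle:
    """Persist segmentation, DER calls, coverage and log2-FC tracks plus a session.

    ``profiles_by_strand`` maps strand -> condition -> list of CoverageProfile;
    ``diff_by_strand`` maps strand -> DifferentialProfile.  Per-condition
    coverage tracks hold the replicate mean of log2(Q + 1).
    """
    os.makedirs(out_dir, exist_ok=True)
    out = str(out_dir)
    segs = [
        GenomicWindow(r.chrom, r.start, r.end, r.strand)
        for r in dea_table.itertuples()
    ]
    lfc = dea_table["log2FoldChange"].to_numpy(dtype=float)
    der_selected = np.asarray(der_selected, dtype=bool)

    def seg_attrs(i: int, is_der: bool) -> dict:
        if is_der:
            color = COLOR_UP if lfc[i] > 0 else COLOR_DOWN
            status = "up" if lfc[i] > 0 else "down"
        else:
            color, status = COLOR_NEUTRAL, "not_der"
        attrs = {"ID": f"segment_{i + 1}", "color": color, "status": status}
        if np.isfinite(lfc[i]):
            attrs["log2FoldChange"] = f"{lfc[i]:.{precision}g}"
        return attrs

    der_idx = np.flatnonzero(der_selected)
    not_idx = np.flatnonzero(~der_selected)
    paths = {
        "der_gff3": os.path.join(out, "ders.gff3"),
        "not_der_gff3": os.path.join(out, "not_ders.gff3"),
        "segmentation_gff3": os.path.join(out, "segmentation.gff3"),
        "segmentation_bed": os.path.join(out, "segmentation.bed"),
    }
    write_gff3(
        [segs[i] for i in der_idx],
        paths["der_gff3"],
        feature_type="DER",
        attributes=[seg_attrs(i, True) for i in der_idx],
        precision=precision,
    )
    write_gff3(
        [segs[i] for i in not_idx],
        paths["not_der_gff3"],
        feature_type="not_DER",
        attributes=[seg_attrs(i, False) for i in not_idx],
        precision=precision,
    )
    write_gff3(
        segs,
        paths["segmentation_gff3"],
        feature_type="segment",
        attributes=[seg_attrs(i, bool(der_selected[i])) for i in range(len(segs))],
        precision=precision,
    )
    write_bed(
        segs,
        paths["segmentation_bed"],
        scores=np.nan_to_num(lfc),
        precision=precision,
    )

    coverage_tracks: list[str] = []
    log2fc_tracks: list[str] = []
    tag = {"+": "plus", "-": "minus"}
    for strand, by_cond in profiles_by_strand.items():
        for cond, profs in by_cond.items():
            mean_log = np.mean([np.log2(p.values + 1.0) for p in profs], axis=0)
            w = profs[0].window
            path = os.path.join(out, f"log2_coverage_{cond}_{tag[strand]}.bedGraph")
            write_bedgraph(
                w.chrom, w.start, mean_log, path,
                track_name=f"log2-Cov {cond} ({strand})", precision=precision,
            )
            coverage_tracks.append(path)
    for strand, diff in diff_by_strand.items():
        path = os.path.join(out, f"log2_fc_{tag[strand]}.bedGraph")
        write_bedgraph(
            diff.window.chrom, diff.window.start, diff.values, path,
            track_name=f"log2-FC ({strand})", precision=precision,
        )
        log2fc_tracks.append(path)

    session = os.path.join(out, "igv_session.xml")
    bundle = ExportBundle(
        der_gff3=paths["der_gff3"],
        not_der_gff3=paths["not_der_gff3"],
        segmentation_gff3=paths["segmentation_gff3"],
        segmentation_bed=paths["segmentation_bed"],
        coverage_bedgraphs=coverage_tracks,
        log2fc_bedgraphs=log2fc_tracks,
        session_xml=session,
    )
    locus = None
    if segs:
        locus = f"{segs[0].chrom}:{min(s.start for s in segs) + 1}-{max(s.end for s in segs)}"
    write_igv_session(
        [p for p in bundle.all_files() if p != session], session,
        genome=genome, locus=locus,
    )
    return bundle
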