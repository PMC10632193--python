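"""Label DERs by their position relative to the nearest annotation.

Each DER is matched to its minimal-distance annotation(s) (distance 0 on
any overlap, strand ignored for the nearest-neighbor search) and the pair
is classified into one of seven strand-aware classes:

    inside               DER contained in a same-strand annotation
    overlapping_5prime   DER crosses only the annotation's 5' boundary
    overlapping_3prime   DER crosses only the annotation's 3' boundary
    overlapping_both     DER crosses both boundaries
    antisense            DER overlaps an opposite-strand annotation
    upstream             no overlap, DER on the annotation's 5' side
    downstream           no overlap, DER on the annotation's 3' side

A DER sharing an endpoint with the annotation does not "cross" it and is
classified inside.  For non-overlapping neighbors the positional label is
computed on the annotation's strand regardless of the DER's strand; the
strand mismatch is recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils

from .windows import GenomicWindow

LABELS = (
    "antisense",
    "upstream",
    "downstream",
    "inside",
    "overlapping_3prime",
    "overlapping_5prime",
    "overlapping_both",
)

NO_ANNOTATION = "no_annotation"


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated feature; coordinates 0-based half-open internally."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class DERLabel:
    der_id: int
    feature_id: str
    label: str
    distance: Optional[int]
    strand_mismatch: bool = False


def classify_pair(der: GenomicWindow, ann: AnnotationRecord) -> str:
    """Classify one overlapping or neighboring (DER, annotation) pair."""
    overlap = der.start < ann.end and ann.start < der.end and der.chrom == ann.chrom
    if overlap:
        if der.strand != ann.strand:
            return "antisense"
        crosses_left = der.start < ann.start
        crosses_right = der.end > ann.end
        if crosses_left and crosses_right:
            return "overlapping_both"
        if not crosses_left and not crosses_right:
            return "inside"
        crossed_5prime = crosses_left if ann.strand == "+" else crosses_right
        return "overlapping_5prime" if crossed_5prime else "overlapping_3prime"
    # disjoint: orient on the annotation's strand
    der_on_left = der.end <= ann.start
    if ann.strand == "+":
        return "upstream" if der_on_left else "downstream"
    return "downstream" if der_on_left else "upstream"


def _distance(der: GenomicWindow, ann: AnnotationRecord) -> int:
    if der.start < ann.end and ann.start < der.end:
        return 0
    return max(ann.start - der.end, der.start - ann.end)


def annotate_nearest(
    ders: Sequence[GenomicWindow],
    annotations: Sequence[AnnotationRecord],
) -> list[DERLabel]:
    """One label per (DER, minimal-distance annotation) pair.

    Distance ties yield one label per tying annotation.  With no
    annotations every DER gets a sentinel ``no_annotation`` record.
    """
    out: list[DERLabel] = []
    for i, der in enumerate(ders):
        same_chrom = [a for a in annotations if a.chrom == der.chrom]
        if not same_chrom:
            out.append(DERLabel(i, NO_ANNOTATION, NO_ANNOTATION, None))
            continue
        dists = [_distance(der, a) for a in same_chrom]
        dmin = min(dists)
        for a, d in zip(same_chrom, dists):
            if d != dmin:
                continue
            label = classify_pair(der, a)
            mismatch = d > 0 and der.strand != a.strand
            out.append(DERLabel(i, a.feature_id, label, d, mismatch))
    return out


def read_annotations(
    path,
    feature_types: Sequence[str] = ("gene",),
    id_attribute: Optional[str] = None,
) -> list[AnnotationRecord]:
    """Load features from GFF3 or GTF into internal 0-based coordinates.

    ``id_attribute`` overrides the identifier key (default: the feature's
    own ID for GFF3, ``gene_id`` for GTF).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records: list[AnnotationRecord] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if feat.strand not in ("+", "-"):
                continue
            if id_attribute and id_attribute in feat.attributes:
                fid = feat.attributes[id_attribute][0]
            elif "gene_id" in feat.attributes and feat.id.startswith("auto"):
                fid = feat.attributes["gene_id"][0]
            else:
                fid = feat.id
            records.append(
                AnnotationRecord(
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF3/GTF are 1-based inclusive
                    end=feat.end,
                    strand=feat.strand,
                    feature_id=fid,
                    feature_type=feat.featuretype,
                )
            )
    return records


def labels_frame(labels: Sequence[DERLabel]):
    """Collapse per-pair labels to one joined string pair per DER index."""
    import pandas as pd

    rows: dict[int, dict[str, str]] = {}
    for lab in labels:
        entry = rows.setdefault(lab.der_id, {"features": [], "labels": []})
        entry["features"].append(lab.feature_id)
        entry["labels"].append(lab.label)
    return pd.DataFrame(
        {
            "der_index": list(rows),
            "nearest_features": [",".join(v["features"]) for v in rows.values()],
            "labels": [",".join(v["labels"]) for v in rows.values()],
        }
    ).set_index("der_index")
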