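import numpy as np
import pysam
import pytest

from derseg.windows import GenomicWindow


def make_bam(path, reads, ref_name="chr1", ref_len=100_000):
    """Write a sorted, indexed BAM from compact read descriptions.

    Each read is a dict with keys pos (0-based), cigar, flag and optional
    tlen, pnext, qname.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }
    reads = sorted(reads, key=lambda r: r["pos"])
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, spec in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = spec.get("qname", f"read_{i}")
            a.reference_id = 0
            a.reference_start = spec["pos"]
            a.cigarstring = spec["cigar"]
            a.flag = spec.get("flag", 0)
            a.mapping_quality = spec.get("mapq", 60)
            length = sum(
                n for op, n in a.cigartuples if op in (0, 1, 4, 7, 8)
            )
            a.query_sequence = "A" * length
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            if "pnext" in spec:
                a.next_reference_id = 0
                a.next_reference_start = spec["pnext"]
            a.template_length = spec.get("tlen", 0)
            bam.write(a)
    pysam.index(path)
    return path


@pytest.fixture
def bam_factory(tmp_path):
    def _factory(reads, name="test.bam", **kwargs):
        return make_bam(tmp_path / name, reads, **kwargs)

    return _factory


@pytest.fixture
def window():
    return GenomicWindow("chr1", 100, 200, "+")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
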