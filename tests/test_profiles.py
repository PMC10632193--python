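import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from derseg.profiles import (
    CoverageProfile,
    end_coverage,
    extract_read_ends,
    full_length_coverage,
    geometric_coverage,
    log2_fc_profile,
    normalization_offset,
    read_units,
)
from derseg.windows import GenomicWindow


def _profile(values, window, condition="a", sample="s1", rep=1, mode="geometric"):
    return CoverageProfile(window, sample, condition, rep, mode, np.asarray(values, float))


class TestExtractReadEnds:
    def test_empty_region_returns_empty_list(self, bam_factory):
        bam = bam_factory([{"pos": 5000, "cigar": "50M"}])
        ends = extract_read_ends(bam, GenomicWindow("chr1", 100, 200, "+"))
        assert ends == []

    def test_forward_read_five_prime_at_start(self, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "50M"}])
        ends = extract_read_ends(bam, GenomicWindow("chr1", 50, 300, "+"))
        assert ends == [(100, 149, "+")]

    def test_reverse_read_swaps_ends(self, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "50M", "flag": 16}])
        ends = extract_read_ends(bam, GenomicWindow("chr1", 50, 300, "+"))
        assert ends == [(149, 100, "-")]

    def test_rf_protocol_flips_strand(self, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "50M"}])
        ends = extract_read_ends(
            bam, GenomicWindow("chr1", 50, 300, "+"), library_protocol="rf"
        )
        assert ends == [(149, 100, "-")]

    def test_secondary_and_unmapped_excluded(self, bam_factory):
        bam = bam_factory(
            [
                {"pos": 100, "cigar": "50M", "flag": 256},  # secondary
                {"pos": 100, "cigar": "50M", "flag": 2048},  # supplementary
                {"pos": 100, "cigar": "50M", "flag": 512},  # qc fail
                {"pos": 110, "cigar": "50M"},
            ]
        )
        ends = extract_read_ends(bam, GenomicWindow("chr1", 50, 300, "+"))
        assert ends == [(110, 159, "+")]

    def test_missing_index_raises(self, tmp_path, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "50M"}])
        (tmp_path / "test.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="index"):
            extract_read_ends(bam, GenomicWindow("chr1", 50, 300, "+"))

    def test_unknown_chrom_raises(self, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "50M"}])
        with pytest.raises(ValueError, match="absent"):
            extract_read_ends(bam, GenomicWindow("chrZ", 50, 300, "+"))

    def test_proper_pair_collapses_to_fragment(self, bam_factory):
        # mates at 100 (fwd) and 200 (rev), fragment [100, 250)
        pair = [
            {"pos": 100, "cigar": "50M", "flag": 99, "pnext": 200, "tlen": 150,
             "qname": "p"},
            {"pos": 200, "cigar": "50M", "flag": 147, "pnext": 100, "tlen": -150,
             "qname": "p"},
        ]
        win = GenomicWindow("chr1", 50, 400, "+")
        frag = extract_read_ends(bam_factory(pair), win, pairing_mode="fragment")
        assert frag == [(100, 249, "+")]
        per_read = extract_read_ends(bam_factory(pair), win, pairing_mode="read")
        # mate-1-based inference puts both mates on the + transcript strand
        assert sorted(per_read) == [(100, 149, "+"), (200, 249, "+")]

    def test_spliced_read_uses_outermost_ends_and_blocks(self, bam_factory):
        bam = bam_factory([{"pos": 100, "cigar": "10M20N10M"}])
        win = GenomicWindow("chr1", 90, 150, "+")
        assert extract_read_ends(bam, win) == [(100, 139, "+")]
        units = read_units(bam, win)
        cov = full_length_coverage(units[0].blocks, win)
        # gap [110, 130) uncovered
        assert cov[10:20].sum() == 10 and cov[20:40].sum() == 0 and cov[40:50].sum() == 10


class TestEndCoverage:
    def test_no_reads_gives_zero_vector(self, window):
        assert end_coverage([], window, "five_prime").sum() == 0

    def test_stacked_and_adjacent_ends(self, window):
        ends = [(110, 150, "+")] * 3 + [(111, 151, "+")]
        cov = end_coverage(ends, window, "five_prime")
        assert cov[10] == 3 and cov[11] == 1 and cov.sum() == 4

    def test_sums_to_reads_with_end_inside_window(self, window):
        ends = [(110, 250, "+"), (50, 150, "+"), (120, 180, "-")]
        assert end_coverage(ends, window, "five_prime").sum() == 1
        assert end_coverage(ends, window, "three_prime").sum() == 1


class TestFullLengthCoverage:
    def test_partial_overlap(self):
        win = GenomicWindow("c", 100, 105, "+")
        assert full_length_coverage([(100, 103)], win).tolist() == [1, 1, 1, 0, 0]

    def test_additivity(self, rng):
        win = GenomicWindow("c", 0, 50, "+")
        starts = rng.integers(0, 45, 20)
        ivs = [(int(s), int(s) + int(rng.integers(1, 6))) for s in starts]
        total = full_length_coverage(ivs, win)
        parts = sum(full_length_coverage([iv], win) for iv in ivs)
        assert np.array_equal(total, parts)


class TestGeometricCoverage:
    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_identity_on_equal_inputs(self, q):
        q = np.asarray(q)
        assert np.allclose(geometric_coverage(q, q), q)

    @pytest.mark.parametrize(
        "q5,q3,expected", [(0, 0, 0.0), (3, 0, 1.0), (1, 7, 3.0)]
    )
    def test_pointwise_values(self, q5, q3, expected):
        assert geometric_coverage([q5], [q3])[0] == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            geometric_coverage([1, 2], [1])


class TestLog2FCProfile:
    def test_identical_profiles_give_zero(self, window):
        p = _profile(np.arange(100), window)
        q = _profile(np.arange(100), window, condition="b")
        assert np.allclose(log2_fc_profile([p], [q]).values, 0.0)

    def test_single_replicate_values(self, window):
        p = _profile(np.full(100, 3.0), window)
        q = _profile(np.full(100, 1.0), window, condition="b")
        assert np.allclose(log2_fc_profile([p], [q]).values, 1.0)

    def test_replicate_averaging(self, window):
        p1 = _profile(np.full(100, 1.0), window)
        p2 = _profile(np.full(100, 3.0), window, sample="s2", rep=2)
        q = _profile(np.zeros(100), window, condition="b")
        # (log2 2 + log2 4)/2 - log2 1 = 1.5
        assert np.allclose(log2_fc_profile([p1, p2], [q]).values, 1.5)

    def test_antisymmetry(self, window, rng):
        ps = [_profile(rng.poisson(5, 100), window, sample=f"a{i}") for i in range(2)]
        qs = [_profile(rng.poisson(9, 100), window, condition="b", sample=f"b{i}")
              for i in range(3)]
        fwd = log2_fc_profile(ps, qs).values
        for q in qs:
            q.condition = "b"
        rev = log2_fc_profile(qs, ps).values
        assert np.allclose(fwd, -rev)

    def test_mixed_windows_rejected(self, window):
        other = GenomicWindow("chr1", 100, 200, "-")
        p = _profile(np.ones(100), window)
        q = CoverageProfile(other, "s", "b", 1, "geometric", np.ones(100))
        with pytest.raises(ValueError, match="share"):
            log2_fc_profile([p], [q])


class TestNormalizationOffset:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [((1, 1), (1, 1), 0.0), ((2,), (1,), 1.0), ((2, 8), (1, 1), 2.0)],
    )
    def test_offset_values(self, s1, s2, expected):
        assert normalization_offset(s1, s2) == pytest.approx(expected)

    def test_nonpositive_factor_raises(self):
        with pytest.raises(ValueError, match="positive"):
            normalization_offset([1.0, 0.0], [1.0])
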