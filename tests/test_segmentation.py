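import numpy as np
import pytest

from derseg.profiles import DifferentialProfile
from derseg.segmentation import (
    PenaltySpec,
    fpop,
    mad_diff_variance,
    optimal_partition_bruteforce,
    penalized_cost,
    sample_variance,
    segment_profile,
)
from derseg.windows import GenomicWindow


class TestSampleVariance:
    @pytest.mark.parametrize(
        "y,expected", [([5, 5, 5], 0.0), ([0, 2], 2.0), ([1, 2, 3], 1.0)]
    )
    def test_values(self, y, expected):
        assert sample_variance(y) == pytest.approx(expected)

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            sample_variance([1.0])

    def test_robust_estimator_ignores_rare_shifts(self, rng):
        y = rng.normal(0, 1, 2000)
        y[1000:] += 50  # one huge shift wrecks the plain estimator
        assert sample_variance(y) > 100
        assert 0.5 < mad_diff_variance(y) < 2.0


class TestFpop:
    def test_constant_signal_single_segment(self):
        r = fpop(np.full(10, 3.3), 2.0)
        assert r.n_changepoints == 0
        assert r.means[0] == pytest.approx(3.3)
        assert r.penalized_cost == pytest.approx(0.0, abs=1e-9)

    def test_clean_step_detected(self):
        r = fpop(np.array([0, 0, 0, 10, 10, 10.0]), 1.0)
        assert r.changepoints.tolist() == [3]
        assert r.means.tolist() == [0.0, 10.0]
        assert r.penalized_cost == pytest.approx(1.0)

    def test_huge_penalty_suppresses_split(self):
        # max SSE reduction is 150 < beta, so one segment is optimal
        r = fpop(np.array([0, 0, 0, 10, 10, 10.0]), 1000.0)
        assert r.n_changepoints == 0
        assert r.means[0] == pytest.approx(5.0)
        assert r.penalized_cost == pytest.approx(150.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fpop(np.array([1.0, np.nan]), 1.0)

    def test_single_point(self):
        r = fpop(np.array([5.0]), 1.0)
        assert r.n_changepoints == 0 and r.penalized_cost == 0.0

    def test_shift_invariance(self, rng):
        for _ in range(10):
            y = rng.normal(size=120)
            y[60:] += 2.0
            beta = 2 * np.var(y, ddof=1) * np.log(y.size)
            base = fpop(y, beta).changepoints
            for c in (-100.0, 3.7, 1e4):
                assert np.array_equal(fpop(y + c, beta).changepoints, base)

    def test_changepoint_count_non_increasing_in_penalty(self, rng):
        y = rng.normal(size=300)
        y[100:200] += 3
        counts = [
            fpop(y, b).n_changepoints for b in np.geomspace(0.01, 1e4, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cost_reconstructable_from_changepoints(self, rng):
        for _ in range(20):
            y = rng.normal(size=rng.integers(2, 150))
            beta = 10 ** rng.uniform(-2, 1)
            r = fpop(y, beta)
            assert penalized_cost(y, r.changepoints, beta) == pytest.approx(
                r.penalized_cost, abs=1e-9
            )


class TestBruteforceOracle:
    def test_single_point(self):
        r = optimal_partition_bruteforce(np.array([5.0]), 3.0)
        assert r.n_changepoints == 0 and r.penalized_cost == 0.0

    def test_zero_penalty_splits_everything(self):
        r = optimal_partition_bruteforce(np.array([0.0, 10.0, 0.0]), 0.0)
        assert r.n_changepoints == 2
        assert r.penalized_cost == pytest.approx(0.0)

    def test_agrees_with_fpop_on_random_signals(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 150))
            y = rng.normal(size=n)
            beta = 10 ** rng.uniform(-2, 1.5)
            a = fpop(y, beta)
            b = optimal_partition_bruteforce(y, beta)
            assert a.penalized_cost == pytest.approx(b.penalized_cost, abs=1e-9)
            assert np.array_equal(a.changepoints, b.changepoints)


class TestPenaltySpec:
    def test_beta_formula(self):
        spec = PenaltySpec(lam=2.0, sigma2_hat=1.5, n=100)
        assert spec.beta == pytest.approx(2.0 * 1.5 * np.log(100))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PenaltySpec(lam=0.0, sigma2_hat=1.0, n=10)
        with pytest.raises(ValueError):
            PenaltySpec(lam=1.0, sigma2_hat=-1.0, n=10)


class TestSegmentProfile:
    def _diff(self, values, strand="+"):
        w = GenomicWindow("c", 1000, 1000 + len(values), strand)
        return DifferentialProfile(w, np.asarray(values, float), 1, 1, "ref")

    def test_constant_profile_single_segment_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            result, segs = segment_profile(self._diff(np.zeros(1000)))
        assert len(segs) == 1
        assert segs[0].start == 1000 and segs[0].end == 2000

    def test_noiseless_step_boundary_exact(self, rng):
        y = np.zeros(1000)
        y[500:] = 3.0
        y += rng.normal(0, 0.05, 1000)
        result, segs = segment_profile(self._diff(y), lam=2.0)
        # independent check against the O(n^2) dynamic program
        sigma2 = sample_variance(y)
        oracle = optimal_partition_bruteforce(y, 2.0 * sigma2 * np.log(1000))
        assert np.array_equal(result.changepoints, oracle.changepoints)
        assert len(segs) == 2
        assert segs[0].end == 1500  # genomic coordinates offset by window start

    def test_huge_lambda_gives_single_segment(self, rng):
        y = np.zeros(1000)
        y[500:] = 3.0
        _, segs = segment_profile(self._diff(y + rng.normal(0, 0.05, 1000)), lam=1e9)
        assert len(segs) == 1

    def test_segments_tile_window_on_both_strands(self, rng):
        y = rng.normal(size=500)
        for strand in "+-":
            _, segs = segment_profile(self._diff(y, strand))
            assert segs[0].start == 1000 and segs[-1].end == 1500
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start and a.strand == strand
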