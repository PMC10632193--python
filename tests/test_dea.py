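import numpy as np
import pandas as pd
import pytest

from derseg.counting import CountMatrix
from derseg.dea import (
    bh_adjust,
    call_ders,
    estimate_dispersion,
    estimate_dispersions,
    median_of_ratios_size_factors,
    nb_wald_table,
    nb_wald_test,
    run_dea,
    simes_fdp_bound,
)
from derseg.windows import GenomicWindow

GROUPS6 = ["a"] * 3 + ["b"] * 3
SF6 = np.ones(6)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [50], [7]], (1, 4))
        assert np.allclose(median_of_ratios_size_factors(counts), 1.0)

    def test_doubled_library_split_symmetrically(self):
        counts = np.array([[10, 20], [50, 100], [7, 14]])
        s = median_of_ratios_size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_rows_with_zeros_excluded_from_reference(self):
        counts = np.array([[10, 20], [50, 100], [0, 1_000_000]])
        s = median_of_ratios_size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_allpositive_row_raises_with_advice(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="poscounts"):
            median_of_ratios_size_factors(counts)
        s = median_of_ratios_size_factors(counts, fallback="poscounts")
        assert np.allclose(np.exp(np.mean(np.log(s))), 1.0)


class TestDispersion:
    def test_all_zero_row_is_untestable(self):
        assert np.isnan(estimate_dispersion([0] * 6, SF6, GROUPS6, "b"))

    def test_poisson_rows_collapse_to_zero(self, rng):
        counts = rng.poisson(500, size=(150, 12))
        d = estimate_dispersions(counts, np.ones(12), ["a"] * 6 + ["b"] * 6, "b")
        assert np.median(d) < 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha, mu, reps = 0.1, 100.0, 20
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(300, 2 * reps))
        d = estimate_dispersions(
            counts, np.ones(2 * reps), ["a"] * reps + ["b"] * reps, "b"
        )
        assert 0.05 < np.median(d) < 0.2


class TestWald:
    def test_identical_groups_give_zero_lfc(self):
        lfc, se, p = nb_wald_test([100] * 6, SF6, 0.1, GROUPS6, "b")
        assert lfc == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_exact_doubling_recovers_lfc_one(self):
        lfc, se, p = nb_wald_test(
            [2000, 2010, 1990, 1000, 1005, 995], SF6, 0.0, GROUPS6, "b"
        )
        assert lfc == pytest.approx(1.0, abs=0.01)
        assert p < 1e-10

    def test_within_group_permutation_invariance(self):
        row = [120, 80, 100, 30, 50, 40]
        base = nb_wald_test(row, SF6, 0.05, GROUPS6, "b")
        permuted = nb_wald_test(
            [80, 100, 120, 50, 40, 30], SF6, 0.05, GROUPS6, "b"
        )
        assert base == pytest.approx(permuted, rel=1e-9)

    def test_one_group_all_zero_flagged_boundary(self):
        res = nb_wald_table(
            np.array([[0, 0, 0, 50, 60, 55]]), SF6, np.array([0.05]), GROUPS6, "b"
        )
        assert bool(res["boundary"][0])
        assert np.isfinite(res["p"][0])

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        sf = np.array([0.8, 1.0, 1.2, 0.9, 1.1, 1.0])
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
        for _ in range(5):
            y = rng.poisson([80, 90, 100, 40, 50, 60])
            alpha = 0.08
            lfc, se, _ = nb_wald_test(y, sf, alpha, GROUPS6, "b")
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf),
            ).fit()
            assert lfc == pytest.approx(glm.params[1] / np.log(2), rel=1e-4)
            assert se == pytest.approx(glm.bse[1] / np.log(2), rel=1e-3)


class TestBH:
    def test_step_up_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        p = rng.uniform(size=100)
        padj = bh_adjust(p)
        assert np.all(padj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(padj[order]) >= -1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestSimesBound:
    def test_two_tiny_pvalues_bound_zero(self):
        p = np.full(100, 0.5)
        p[:2] = 1e-6
        assert simes_fdp_bound(p, [0, 1], 0.05) == (0, 0.0)

    def test_two_unit_pvalues_bound_one(self):
        p = np.full(100, 0.5)
        p[:2] = 1.0
        assert simes_fdp_bound(p, [0, 1], 0.05) == (2, 1.0)

    def test_mixed_selection_intermediate_bound(self):
        # k=1: 1 + 0 = 1;  k=2: 1 + 1 = 2  ->  v_bar = 1, bound 1/2
        p = np.full(100, 0.5)
        p[0], p[1] = 1e-4, 2e-3
        assert simes_fdp_bound(p, [0, 1], 0.05) == (1, 0.5)

    def test_empty_selection(self):
        assert simes_fdp_bound(np.full(10, 0.5), [], 0.05) == (0, 0.0)

    def test_bound_non_increasing_as_p_decreases(self, rng):
        p = rng.uniform(size=50)
        sel = np.arange(10)
        _, before = simes_fdp_bound(p, sel, 0.05)
        p2 = p.copy()
        p2[3] /= 10
        _, after = simes_fdp_bound(p2, sel, 0.05)
        assert after <= before

    def test_permutation_invariant_selection(self, rng):
        p = rng.uniform(size=50)
        sel = np.array([4, 8, 15, 16, 23, 42])
        assert simes_fdp_bound(p, sel, 0.05) == simes_fdp_bound(
            p, sel[::-1], 0.05
        )


def _dea_frame(p, lfc, start=None):
    return pd.DataFrame(
        {
            "pvalue": p,
            "log2FoldChange": lfc,
            "start": np.arange(len(p)) if start is None else start,
        }
    )


class TestCallDers:
    def test_no_candidate_passes_fc_threshold(self):
        call = call_ders(_dea_frame([0.001, 0.002], [0.1, -0.2]))
        assert not call.selected.any() and call.fdp_bound == 0.0

    def test_all_tiny_p_all_selected(self):
        call = call_ders(_dea_frame([1e-8] * 5, [2.0] * 5))
        assert call.selected.all() and call.v_bar == 0

    def test_selection_matches_exhaustive_prefix_search(self, rng):
        for _ in range(20):
            m = 40
            p = rng.uniform(size=m) ** 2
            lfc = rng.normal(0, 1.5, m)
            df = _dea_frame(p, lfc)
            call = call_ders(df)
            cand = np.flatnonzero(np.abs(lfc) > np.log2(1.5))
            order = cand[np.lexsort((np.arange(m)[cand], p[cand]))]
            best = 0
            for L in range(1, order.size + 1):
                _, bound = simes_fdp_bound(p, order[:L], 0.05)
                if bound <= 0.05:
                    best = L
            assert call.selected.sum() == best

    def test_invariant_to_row_order(self, rng):
        p = rng.uniform(size=30) ** 3
        lfc = rng.normal(0, 1.5, 30)
        df = _dea_frame(p, lfc)
        perm = rng.permutation(30)
        df2 = df.iloc[perm].reset_index(drop=True)
        sel1 = np.flatnonzero(call_ders(df).selected)
        sel2 = perm[np.flatnonzero(call_ders(df2).selected)]
        assert sorted(sel1) == sorted(sel2)


class TestRunDea:
    def _matrix(self, counts, conditions):
        n = counts.shape[0]
        segs = [GenomicWindow("c", i * 10, (i + 1) * 10, "+") for i in range(n)]
        samples = [(f"s{j}", c, j + 1) for j, c in enumerate(conditions)]
        return CountMatrix(segs, samples, counts)

    def test_structural_contract(self, rng):
        counts = rng.poisson(50, size=(30, 6))
        counts[0] = 0  # untestable row
        tab = run_dea(self._matrix(counts, GROUPS6), "b", fallback="poscounts")
        assert not tab["tested"][0] and np.isnan(tab["pvalue"][0])
        ok = tab["pvalue"].notna()
        assert np.all(tab.loc[ok, "padj"] >= tab.loc[ok, "pvalue"] - 1e-12)
        assert tab.attrs["m_tested"] == 29
        assert np.isfinite(tab.attrs["rho"])

    def test_reference_condition_orientation(self):
        # unit size factors isolate the orientation of the contrast
        counts = np.tile([200, 210, 190, 50, 55, 45], (20, 1))
        sf = np.ones(6)
        tab = run_dea(self._matrix(counts, GROUPS6), "b", size_factors=sf)
        assert (tab["log2FoldChange"] > 1.5).all()  # a vs reference b is up
        tab_flipped = run_dea(self._matrix(counts, GROUPS6), "a", size_factors=sf)
        assert (tab_flipped["log2FoldChange"] < -1.5).all()
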