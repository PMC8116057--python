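"""Unit and property tests for the EMD statistic, the permutation test,
BH correction, the full differential run, and the manual SOP screen."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import endshift as es
from endshift.emd import (
    CALL_DISTAL, CALL_NS, CALL_PROXIMAL, CALL_UNTESTED,
    cluster_sites, empirical_pvalue,
)
from endshift.read_io import ThreePrimeProfile, ValidationError


def sorted_pairing_emd(x, y):
    """Equal-n oracle: (1/n) sum |x_(i) - y_(i)|."""
    assert len(x) == len(y)
    return np.mean(np.abs(np.sort(x) - np.sort(y)))


def exhaustive_permutation_p(x, y):
    """Exact permutation p by enumerating every split of the pooled
    sample into groups of the original sizes."""
    pooled = np.concatenate([x, y]).astype(float)
    n, nx = pooled.size, len(x)
    observed = es.wasserstein_distance(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        total += 1
        if es.wasserstein_distance(pooled[mask], pooled[~mask]) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestWassersteinDistance:
    @pytest.mark.parametrize("x, y, expected", [
        ([100, 100], [100, 100], 0.0),
        ([0], [100], 100.0),
        ([0, 0, 100], [0, 100, 100], 100 / 3),
    ])
    def test_small_examples(self, x, y, expected):
        assert es.wasserstein_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sorted_pairing_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            x = rng.integers(0, 5000, n)
            y = rng.integers(0, 5000, n)
            assert es.wasserstein_distance(x, y) == pytest.approx(
                sorted_pairing_emd(x, y), abs=1e-9)

    def test_unequal_n_agrees_with_independent_implementation(self, rng):
        for _ in range(200):
            x = rng.integers(0, 5000, int(rng.integers(1, 50)))
            y = rng.integers(0, 5000, int(rng.integers(1, 50)))
            assert es.wasserstein_distance(x, y) == pytest.approx(
                scipy.stats.wasserstein_distance(x, y), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            es.wasserstein_distance([], [1, 2])

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=30),
           st.lists(st.integers(0, 10_000), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, x, y):
        d = es.wasserstein_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(es.wasserstein_distance(y, x), abs=1e-9)

    @given(st.lists(st.integers(-5000, 5000), min_size=1, max_size=25),
           st.integers(-2000, 2000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_translation_property(self, x, d):
        shifted = [v + d for v in x]
        assert es.wasserstein_distance(shifted, x) == pytest.approx(abs(d), abs=1e-9)

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=10),
           st.lists(st.integers(0, 500), min_size=1, max_size=10),
           st.lists(st.integers(0, 500), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_triangle_inequality(self, x, y, z):
        dxz = es.wasserstein_distance(x, z)
        assert dxz <= (es.wasserstein_distance(x, y)
                       + es.wasserstein_distance(y, z) + 1e-9)

    def test_zero_iff_equal_empirical_distributions(self):
        assert es.wasserstein_distance([1, 2, 1, 2], [2, 1, 2, 1]) == 0
        # same multiset ratio, different n: equal distributions
        assert es.wasserstein_distance([1, 2], [1, 1, 2, 2]) == 0
        assert es.wasserstein_distance([1, 2], [1, 3]) > 0


class TestMeanShift:
    @pytest.mark.parametrize("strand, expected", [("+", 200.0), ("-", -200.0)])
    def test_sign_convention(self, strand, expected):
        assert es.mean_shift([500, 500], [300, 300], strand) == expected

    def test_identical_samples_zero(self):
        assert es.mean_shift([10, 20], [10, 20], "+") == 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            es.mean_shift([], [1], "+")


class TestPermutationPvalue:
    def test_identical_multisets_give_p_one(self, rng):
        x = [100, 150, 200]
        p, _ = es.permutation_pvalue(x, list(x), es.EMDTestConfig(seed=0), rng)
        assert p == 1.0

    def test_exhaustive_example_two_point_masses(self):
        # all C(6,3)=20 splits of {0,0,0,300,300,300}; exactly 2 reach
        # the observed EMD of 300
        p_exact = exhaustive_permutation_p([0, 0, 0], [300, 300, 300])
        assert p_exact == pytest.approx(0.1)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        x, y = [0, 0, 0], [300, 300, 300]
        config = es.EMDTestConfig(n_permutations=20_000, seed=3)
        p_mc, _ = es.permutation_pvalue(x, y, config, rng, mode="empirical")
        se = np.sqrt(0.1 * 0.9 / config.n_permutations)
        assert abs(p_mc - 0.1) < 3 * se + 1e-4

    def test_low_observed_emd_gives_large_p(self, rng):
        # treatment barely different from control: observed EMD sits
        # below the null median, so p > 0.5 under both estimators
        x = np.array([0, 100, 200, 300, 400, 500])
        y = x + 1
        for mode in ("gamma", "empirical"):
            p, _ = es.permutation_pvalue(
                x, y, es.EMDTestConfig(seed=5), np.random.default_rng(5), mode=mode)
            assert p > 0.5

    def test_gamma_p_monotone_in_observed_emd(self):
        null = np.abs(np.random.default_rng(0).normal(10, 3, 999)) + 0.1
        from endshift.emd import _fit_gamma_tail
        shape, scale, ok = _fit_gamma_tail(null, "mle_loc0")
        assert ok
        grid = np.linspace(0, 50, 40)
        sf = scipy.stats.gamma.sf(grid, shape, scale=scale)
        assert np.all(np.diff(sf) <= 0)

    def test_degenerate_null_falls_back_to_empirical(self, rng):
        # all pooled values identical apart from one: null EMDs contain
        # zeros, so the gamma MLE is degenerate
        p, dist = es.permutation_pvalue(
            [0, 0, 0, 0, 0], [0, 0, 0, 0, 50], es.EMDTestConfig(seed=2), rng)
        assert not dist.fit_ok or p > 0
        assert 0 < p <= 1

    def test_empirical_pvalue_convention(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_pvalue(null, 3.5) == pytest.approx(2 / 5)
        assert empirical_pvalue(null, 0.0) == 1.0


class TestBHAdjust:
    def test_hand_computed_example(self):
        # BH on (0.01, 0.02, 0.03, 0.04): 0.04*4/4=0.04 then step-up
        # makes all four 0.04
        np.testing.assert_allclose(
            es.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_unit_pvalues(self):
        assert es.bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(es.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            es.bh_adjust([0.1, np.nan])


def _profile(locus, condition, positions, strand="+"):
    return ThreePrimeProfile(locus, condition, np.asarray(positions), strand)


class TestRunDifferential:
    def test_shifted_locus_called_among_nulls(self, rng):
        from endshift import simulate as sim
        specs = [sim.make_null_spec(f"null{i:02d}", start=i * 10_000) for i in range(50)]
        specs.append(sim.make_shifted_spec("shifted", start=50 * 10_000))
        trt, ctl, truth = sim.simulate_three_prime_dataset(specs, seed=11)
        results = es.run_differential_three_prime(trt, ctl, es.EMDTestConfig(seed=11))
        by_id = {r.locus_id: r for r in results}
        assert by_id["shifted"].call == CALL_DISTAL
        # observed EMD near the analytic population value of 120 nt
        assert by_id["shifted"].emd == pytest.approx(120, abs=40)

    def test_emd_threshold_is_strict(self):
        # EMD exactly 25: significant p but not called (threshold is >25)
        trt = {"loc": _profile("loc", "treatment", [0] * 30)}
        ctl = {"loc": _profile("loc", "control", [25] * 30)}
        (res,) = es.run_differential_three_prime(trt, ctl, es.EMDTestConfig(seed=1))
        assert res.emd == 25.0
        assert res.call == CALL_NS

    def test_insufficient_reads_flagged_untested(self):
        trt = {"loc": _profile("loc", "treatment", [0, 1, 2])}
        ctl = {"loc": _profile("loc", "control", [500] * 30)}
        (res,) = es.run_differential_three_prime(trt, ctl, es.EMDTestConfig(seed=1))
        assert res.call == CALL_UNTESTED
        assert np.isnan(res.p_value) and np.isnan(res.fdr)

    def test_deterministic_and_iteration_order_invariant(self):
        from endshift import simulate as sim
        specs = [sim.make_null_spec(f"n{i}", start=i * 10_000) for i in range(5)]
        specs.append(sim.make_shifted_spec("s0", start=60_000))
        trt, ctl, _ = sim.simulate_three_prime_dataset(specs, seed=2)
        config = es.EMDTestConfig(seed=2)
        frame1 = es.results_to_frame(es.run_differential_three_prime(trt, ctl, config))
        reordered_trt = dict(reversed(list(trt.items())))
        reordered_ctl = dict(reversed(list(ctl.items())))
        frame2 = es.results_to_frame(
            es.run_differential_three_prime(reordered_trt, reordered_ctl, config))
        assert frame1.to_csv() == frame2.to_csv()

    def test_strand_mismatch_rejected(self):
        trt = {"loc": _profile("loc", "treatment", [0] * 10, "+")}
        ctl = {"loc": _profile("loc", "control", [0] * 10, "-")}
        with pytest.raises(ValidationError):
            es.run_differential_three_prime(trt, ctl, es.EMDTestConfig(seed=1))

    def test_proximal_call_on_negative_shift(self):
        trt = {"loc": _profile("loc", "treatment", [100] * 30)}
        ctl = {"loc": _profile("loc", "control", [500] * 30)}
        (res,) = es.run_differential_three_prime(trt, ctl, es.EMDTestConfig(seed=1))
        assert res.call == CALL_PROXIMAL
        assert res.mean_shift == -400


class TestSopScreen:
    def test_single_condition_not_expressed(self):
        out = es.sop_screen({"col0": [100, 110], "mutant": []})
        assert not out["expressed"]

    def test_cluster_support_threshold(self):
        # clusters of 4 and 3 pooled reads: below the 4-read rule
        out = es.sop_screen({
            "col0": [100, 101, 102, 103], "mutant": [500, 501, 502]})
        assert out["expressed"] and not out["multi_site"]

    def test_reciprocal_usage_is_apa_candidate(self):
        out = es.sop_screen({
            "col0": [100] * 9 + [500], "mutant": [100] + [500] * 9},
            coverage_fold=2.0)
        assert out["multi_site"] and out["apa_candidate"]

    def test_balanced_usage_not_candidate(self):
        out = es.sop_screen({
            "col0": [100] * 5 + [500] * 5, "mutant": [100] * 5 + [500] * 5},
            coverage_fold=2.0)
        assert out["multi_site"] and not out["apa_candidate"]

    def test_cluster_sites_single_linkage(self):
        clusters = cluster_sites([0, 5, 10, 40, 45], cluster_window=13)
        assert [list(c) for c in clusters] == [[0, 5, 10], [40, 45]]
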