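import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from corrshape import (
    AnalysisRegion,
    Correlogram,
    CorrelogramSpec,
    MetricParams,
    SpikeTrain,
    area_left_of_zero,
    build_correlogram,
    chi_squared_uniformity,
    compute_metrics,
    count_and_time_peaks,
    find_peaks,
    make_bins,
    smooth_correlogram,
)


def cg_from_counts(counts, n_ref=100, n_cmp=100):
    counts = np.asarray(counts, dtype=np.int64)
    K = counts.size // 2
    centers = (np.arange(counts.size) - K) * 0.001
    return Correlogram("a", "b", 1, centers, counts, n_ref, n_cmp)


class TestChiSquaredUniformity:
    def test_flat_counts_give_zero_statistic(self):
        chi2, p, uniform = chi_squared_uniformity(cg_from_counts([5, 5, 5, 5, 5]))
        assert chi2 == 0.0
        assert p == 1.0
        assert uniform

    def test_concentrated_counts_hand_computed(self):
        # counts [10,0,0,0]: E = 2.5, pearson chi2 = (7.5^2 + 3*2.5^2)/2.5 = 30
        cg = cg_from_counts([10, 0, 0, 0])
        chi2, p, uniform = chi_squared_uniformity(cg)
        assert chi2 == pytest.approx(30.0)
        assert p == pytest.approx(stats.chi2.sf(30.0, 3), rel=1e-12)
        assert not uniform

    def test_as_printed_variant_drops_normalization(self):
        cg = cg_from_counts([10, 0, 0, 0])
        chi2, _, _ = chi_squared_uniformity(
            cg, MetricParams(chi2_variant="as_printed")
        )
        assert chi2 == pytest.approx(75.0)  # sum (O-E)^2 with E=2.5

    def test_p_exactly_at_alpha_is_nonuniform(self):
        cg = cg_from_counts([10, 0, 0, 0])
        _, p, _ = chi_squared_uniformity(cg)
        _, _, uniform = chi_squared_uniformity(cg, MetricParams(alpha=p))
        assert not uniform

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chi_squared_uniformity(cg_from_counts([0, 0, 0]))

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=12).filter(lambda c: sum(c) > 0),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_pearson_invariant_under_bin_permutation(self, counts, rnd):
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        c1, _, _ = chi_squared_uniformity(cg_from_counts(counts))
        c2, _, _ = chi_squared_uniformity(cg_from_counts(shuffled))
        assert c1 == pytest.approx(c2)

    def test_concentration_never_decreases_chi2(self):
        # moving a count from a poorer bin to a richer bin (majorization step)
        base = [6, 4, 3, 2]
        conc = [7, 4, 3, 1]
        c1, _, _ = chi_squared_uniformity(cg_from_counts(base))
        c2, _, _ = chi_squared_uniformity(cg_from_counts(conc))
        assert c2 >= c1


class TestSmoothCorrelogram:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(51))
        np.testing.assert_array_equal(smooth_correlogram(probs, 1), probs)

    @pytest.mark.parametrize("window", [5, 9, 15])
    def test_reproduces_quadratics_away_from_edges(self, window):
        L = 101
        k = np.arange(L, dtype=float)
        probs = 2.0 + 0.03 * k + 0.004 * k * k
        probs /= probs.sum()
        sm = smooth_correlogram(probs, window)
        h = window // 2
        np.testing.assert_allclose(sm[h:-h], probs[h:-h], atol=1e-9)

    def test_constant_preserved_everywhere(self):
        probs = np.full(31, 1 / 31)
        np.testing.assert_allclose(smooth_correlogram(probs, 7), probs, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_correlogram(np.ones(10), 4)


class TestFindPeaks:
    def test_constant_has_no_peaks(self):
        idx, _ = find_peaks(np.full(101, 0.01), 0.001)
        assert idx.size == 0

    def test_single_delta_is_one_peak(self):
        x = np.zeros(2001)
        x[700] = 1.0
        idx, prom = find_peaks(x, 1 / 2001)
        assert list(idx) == [700]
        assert prom[0] == pytest.approx(1.0)

    def test_three_isolated_bumps(self):
        L = 101
        x = np.full(L, 1 / L)
        for center in (20, 50, 80):
            x[center] += 3 / L
        idx, _ = find_peaks(x, 1 / L)
        assert list(idx) == [20, 50, 80]

    def test_prominence_floor_is_strict(self):
        L = 101
        x = np.full(L, 1 / L)
        x[50] += 1 / L  # prominence exactly 1/L: must NOT count
        idx, _ = find_peaks(x, 1 / L)
        assert idx.size == 0

    def test_endpoints_never_peaks(self):
        x = np.linspace(0, 1, 50)
        idx, _ = find_peaks(x, 0.0)
        assert idx.size == 0

    def test_mirrored_input_mirrors_peaks(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(201))
        i1, _ = find_peaks(x, 1 / 201)
        i2, _ = find_peaks(x[::-1], 1 / 201)
        np.testing.assert_array_equal(np.sort(200 - i2), i1)


class TestCountAndTimePeaks:
    def test_uniform_correlogram_no_peaks(self):
        cg = cg_from_counts([4] * 21)
        n, times = count_and_time_peaks(cg, MetricParams(smooth_window=1))
        assert n == 0 and times.size == 0

    def test_delta_at_plus_10ms(self):
        counts = np.zeros(2001, dtype=int)
        counts[1000 + 10] = 50
        cg = cg_from_counts(counts)
        n, times = count_and_time_peaks(cg, MetricParams(smooth_window=1))
        assert n == 1
        assert times[0] == pytest.approx(0.010)

    def test_periodic_bumps_counted(self):
        # bumps at 0, +-0.25, +-0.5, +-0.75 s within +-1 s
        spec = CorrelogramSpec(1.0, 0.001)
        counts = np.zeros(spec.n_bins, dtype=int)
        for lag_ms in (-750, -500, -250, 0, 250, 500, 750):
            counts[1000 + lag_ms] = 30
        cg = cg_from_counts(counts)
        n, times = count_and_time_peaks(cg, MetricParams(smooth_window=5))
        assert n == 7
        np.testing.assert_allclose(
            np.sort(times), [-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75], atol=1e-9
        )


class TestAreaLeftOfZero:
    def test_half_split_worked_example(self):
        cg = cg_from_counts([20, 30, 10, 25, 15])
        assert area_left_of_zero(cg) == pytest.approx(0.55)

    def test_symmetric_counts_give_half(self):
        cg = cg_from_counts([3, 7, 11, 7, 3])
        assert area_left_of_zero(cg) == pytest.approx(0.5)

    def test_literal_variant_excludes_center(self):
        cg = cg_from_counts([20, 30, 10, 25, 15])
        assert area_left_of_zero(cg, half_center=False) == pytest.approx(0.5)

    def test_mirror_complementarity_exact(self):
        rng = np.random.default_rng(7)
        spec = CorrelogramSpec(0.05, 0.005)
        region = AnalysisRegion(1, 0.0, 20.0)
        for _ in range(20):
            a = SpikeTrain("a", np.sort(rng.uniform(0, 20, 40)))
            b = SpikeTrain("b", np.sort(rng.uniform(0, 20, 40)))
            ij = build_correlogram(a, b, spec, region)
            ji = build_correlogram(b, a, spec, region)
            if ij.total == 0:
                continue
            assert area_left_of_zero(ij) + area_left_of_zero(ji) == pytest.approx(1.0, abs=1e-12)

    def test_autocorrelogram_area_is_half(self):
        rng = np.random.default_rng(8)
        spec = CorrelogramSpec(0.05, 0.005)
        a = SpikeTrain("a", np.sort(rng.uniform(0, 20, 80)))
        auto = build_correlogram(a, a, spec, AnalysisRegion(1, 0.0, 20.0))
        assert area_left_of_zero(auto) == pytest.approx(0.5, abs=1e-12)


class TestComputeMetrics:
    def test_sparse_input_yields_none(self):
        cg = cg_from_counts([0, 0, 0, 0, 0])
        assert compute_metrics(cg) is None

    def test_low_expected_count_flagged(self):
        cg = cg_from_counts([1, 0, 2, 0, 1])
        sm = compute_metrics(cg, MetricParams(smooth_window=1))
        assert sm.expected_count_warning

    def test_full_metrics_on_dense_correlogram(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, size=21)
        sm = compute_metrics(cg_from_counts(counts))
        assert 0 <= sm.p_value <= 1
        assert 0 <= sm.area_left <= 1
        assert sm.peak_count >= 0
        assert not sm.expected_count_warning
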