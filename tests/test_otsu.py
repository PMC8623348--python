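"""Histogram machinery and exact multilevel Otsu search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iimtseg import (
    GrayHistogram,
    between_class_variance,
    class_stats,
    compute_histogram,
    otsu_multilevel,
    otsu_single_in_interval,
)
from iimtseg.otsu import InfeasibleKError, InvalidImageError, InvalidIntervalError

from conftest import random_histogram
from oracles import otsu_exhaustive_full_range, otsu_exhaustive_occupied, sigma_b_direct


class TestHistogram:
    def test_direct_counts(self):
        h = compute_histogram(np.array([[0, 0], [128, 255]]))
        assert h.probabilities[0] == 0.5
        assert h.probabilities[128] == 0.25
        assert h.probabilities[255] == 0.25
        assert h.probabilities.sum() == 1.0
        assert np.count_nonzero(h.probabilities) == 3

    def test_constant_image(self):
        h = compute_histogram(np.full((7, 3), 42))
        assert h.probabilities[42] == 1.0
        assert h.counts[42] == 21

    def test_conservation(self, rng):
        img = rng.integers(0, 256, size=(10, 10))
        h = compute_histogram(img)
        assert h.counts.sum() == 100
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        np.array([[0.5, 1.0]]),          # non-integer
        np.array([[-1, 0]]),             # negative
        np.array([[0, 256]]),            # above range
    ])
    def test_invalid_pixels_rejected(self, bad):
        with pytest.raises(InvalidImageError):
            compute_histogram(bad)


class TestClassStats:
    def test_two_spikes(self, two_spike_hist):
        st_ = class_stats(two_spike_hist, [0])
        assert st_.weights == pytest.approx([0.5, 0.5])
        assert st_.means == pytest.approx([0.0, 255.0])
        assert st_.total_mean == pytest.approx(127.5)

    def test_empty_class_mean_is_zero(self):
        p = np.zeros(256)
        p[100] = 1.0
        st_ = class_stats(GrayHistogram.from_probabilities(p), [50])
        assert st_.weights == pytest.approx([0.0, 1.0])
        assert st_.means == pytest.approx([0.0, 100.0])
        assert st_.total_mean == pytest.approx(100.0)

    def test_uniform_histogram(self, uniform_hist):
        st_ = class_stats(uniform_hist, [127])
        assert st_.weights == pytest.approx([0.5, 0.5])
        assert st_.means == pytest.approx([63.5, 191.5])
        assert st_.total_mean == pytest.approx(127.5)

    def test_weights_sum_and_mean_identity(self, rng):
        for _ in range(20):
            h = random_histogram(rng, int(rng.integers(4, 40)))
            t = sorted(rng.choice(254, size=3, replace=False))
            st_ = class_stats(h, t)
            assert st_.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert st_.weights @ st_.means == pytest.approx(st_.total_mean, abs=1e-9)
            assert np.all(np.diff(st_.means[st_.weights > 0]) >= 0)


class TestBetweenClassVariance:
    def test_single_populated_class_is_zero(self):
        p = np.zeros(256)
        p[77] = 1.0
        h = GrayHistogram.from_probabilities(p)
        assert between_class_variance(h, [100]) == 0.0

    def test_two_spikes_hand_value(self, two_spike_hist):
        assert between_class_variance(two_spike_hist, [0]) == pytest.approx(16256.25)

    def test_two_spikes_invariant_over_separating_thresholds(self, two_spike_hist):
        values = [between_class_variance(two_spike_hist, [t]) for t in range(255)]
        assert all(v == pytest.approx(16256.25) for v in values)

    def test_permutation_invariance(self, rng):
        img = rng.integers(0, 256, size=(12, 9))
        shuffled = rng.permutation(img.ravel()).reshape(9, 12)
        h1, h2 = compute_histogram(img), compute_histogram(shuffled)
        assert between_class_variance(h1, [80, 160]) == pytest.approx(
            between_class_variance(h2, [80, 160])
        )

    def test_law_of_total_variance(self, rng):
        levels = np.arange(256, dtype=float)
        for _ in range(20):
            h = random_histogram(rng, int(rng.integers(8, 64)))
            t = sorted(int(x) for x in rng.choice(254, size=2, replace=False))
            p = h.probabilities
            total_var = float(p @ (levels - p @ levels) ** 2)
            st_ = class_stats(h, t)
            within = 0.0
            edges = [-1] + list(t) + [255]
            for i in range(len(edges) - 1):
                lo, hi = edges[i] + 1, edges[i + 1]
                w = p[lo : hi + 1].sum()
                if w > 0:
                    mu = (levels[lo : hi + 1] * p[lo : hi + 1]).sum() / w
                    within += float(
                        (p[lo : hi + 1] * (levels[lo : hi + 1] - mu) ** 2).sum()
                    )
            sigma_b = between_class_variance(h, t)
            assert sigma_b + within == pytest.approx(total_var, abs=1e-6)


class TestOtsuMultilevel:
    def test_two_spikes_smallest_tied_maximizer(self, two_spike_hist):
        assert otsu_multilevel(two_spike_hist, 1).tolist() == [0]
        assert otsu_exhaustive_full_range(two_spike_hist.probabilities, 1) == (0,)

    def test_three_spikes_lexicographic_tie_break(self):
        p = np.zeros(256)
        p[[0, 128, 255]] = 1 / 3
        h = GrayHistogram.from_probabilities(p)
        assert otsu_multilevel(h, 2).tolist() == [0, 128]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_exhaustive_oracle(self, rng, k):
        for _ in range(25):
            h = random_histogram(rng, int(rng.integers(16, 65)))
            got = tuple(otsu_multilevel(h, k).tolist())
            assert got == otsu_exhaustive_occupied(h.probabilities, k)

    def test_matches_full_range_oracle_narrow_support(self, rng):
        # full-range enumeration is feasible when the search is narrow
        h = random_histogram(rng, 10, span=24)
        got = tuple(otsu_multilevel(h, 2).tolist())
        assert got == otsu_exhaustive_occupied(h.probabilities, 2)
        p = h.probabilities
        assert sigma_b_direct(p, got) == pytest.approx(
            between_class_variance(h, got)
        )

    def test_k4_dp_agrees_with_occupied_oracle(self, rng):
        for _ in range(5):
            h = random_histogram(rng, 20)
            got = tuple(otsu_multilevel(h, 4).tolist())
            assert got == otsu_exhaustive_occupied(h.probabilities, 4)

    def test_infeasible_k(self):
        p = np.zeros(256)
        p[[3, 200]] = 0.5
        h = GrayHistogram.from_probabilities(p)
        with pytest.raises(InfeasibleKError):
            otsu_multilevel(h, 2)


class TestOtsuSingleInInterval:
    def test_two_spikes_in_interval(self):
        p = np.zeros(256)
        p[[10, 20]] = 0.5
        h = GrayHistogram.from_probabilities(p)
        t, lo, hi, degen = otsu_single_in_interval(h, 5, 25)
        assert (t, lo, hi, degen) == (10, 10.0, 20.0, False)

    def test_single_occupied_bin_degenerate(self):
        p = np.zeros(256)
        p[42] = 1.0
        h = GrayHistogram.from_probabilities(p)
        t, lo, hi, degen = otsu_single_in_interval(h, 40, 44)
        assert degen and t == 42 and (lo, hi) == (40.0, 44.0)

    def test_full_interval_is_global_single_otsu(self, rng):
        h = random_histogram(rng, 30)
        t, *_ , degen = otsu_single_in_interval(h, 0, 255)
        assert not degen
        assert t == int(otsu_multilevel(h, 1)[0])

    def test_invalid_interval(self, uniform_hist):
        with pytest.raises(InvalidIntervalError):
            otsu_single_in_interval(uniform_hist, 10, 5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 3))
def test_otsu_oracle_equivalence_property(seed, k):
    """DP search equals independent exhaustive enumeration, any seed."""
    rng = np.random.default_rng(seed)
    h = random_histogram(rng, int(rng.integers(k + 1, 32)))
    if np.count_nonzero(h.probabilities) < k + 1:
        return
    assert tuple(otsu_multilevel(h, k).tolist()) == otsu_exhaustive_occupied(
        h.probabilities, k
    )
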