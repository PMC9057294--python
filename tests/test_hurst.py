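"""R/S rescaled-range analysis, Hurst estimation, and future-trend classes."""

import itertools

import numpy as np
import pytest

from vegdyn.hurst import (
    FUTURE_CLASSES,
    H_CLASSES,
    HurstGrid,
    classify_future,
    classify_hurst,
    default_windows,
    estimate_hurst,
    hurst_grid,
    rescaled_range,
)
from vegdyn.stack import AnnualStack
from vegdyn.synthetic import fgn


def brute_rs(x, window, cumulated=True):
    """Independent window-by-window R/S oracle."""
    vals = []
    for start in range(0, len(x) - window + 1, window):
        seg = np.asarray(x[start:start + window], dtype=float)
        m = seg.mean()
        dev = seg - m
        spread = np.cumsum(dev) if cumulated else dev
        R = spread.max() - spread.min()
        S = np.sqrt(((seg - m) ** 2).mean())
        if S > 0:
            vals.append(R / S)
    return np.mean(vals)


class TestRescaledRange:
    def test_alternating_series_hand_computed(self):
        # window 2 on (0,1,0,1,...): deviations (-.5,+.5), cumulated (-.5,0),
        # R = 0.5, S = 0.5 => R/S = 1 in every window
        x = np.tile([0.0, 1.0], 8)
        assert rescaled_range(x, 2) == pytest.approx(1.0, rel=1e-14)

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescaled_range(np.full(16, 0.3), 4)

    def test_single_window_matches_brute_force(self, rng):
        x = rng.normal(size=64)
        assert rescaled_range(x, 64) == pytest.approx(brute_rs(x, 64), rel=1e-12)

    def test_multi_window_matches_brute_force(self, rng):
        x = rng.normal(size=100)
        for w in (4, 10, 25, 33):
            assert rescaled_range(x, w) == pytest.approx(brute_rs(x, w), rel=1e-12)

    def test_literal_variant_ranges_raw_deviations(self, rng):
        x = rng.normal(size=64)
        lit = rescaled_range(x, 32, literal_eq5=True)
        assert lit == pytest.approx(brute_rs(x, 32, cumulated=False), rel=1e-12)
        assert lit != pytest.approx(rescaled_range(x, 32), rel=1e-6)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            rescaled_range(np.arange(10.0), 1)
        with pytest.raises(ValueError):
            rescaled_range(np.arange(10.0), 11)


class TestEstimateHurst:
    def test_white_noise_near_half(self, rng):
        x = rng.standard_normal((1024, 100))
        H = estimate_hurst(x)
        assert 0.45 <= H.mean() <= 0.60

    def test_deterministic_ramp_strongly_persistent(self):
        x = np.arange(256, dtype=float) / 256
        assert estimate_hurst(x) > 0.9

    def test_scale_and_shift_invariance(self, rng):
        x = rng.standard_normal(256)
        h0 = estimate_hurst(x)
        assert estimate_hurst(3.7 * x + 11.0) == pytest.approx(h0, rel=1e-10)

    def test_monotone_recovery_across_planted_h(self):
        """Mean estimated H increases strictly with the planted exponent."""
        means = []
        for i, H in enumerate([0.3, 0.5, 0.7, 0.9]):
            x = fgn(H, 1024, 60, np.random.default_rng(100 + i))
            means.append(estimate_hurst(x.T).mean())
        assert np.all(np.diff(means) > 0)

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            estimate_hurst(rng.normal(size=32), windows=[4, 8])

    def test_short_series_window_set(self):
        assert default_windows(21) == [4, 5, 6, 7, 8, 9, 10, 21]

    def test_long_series_windows_span_32_to_half(self):
        w = default_windows(4096)
        assert w[0] == 32 and w[-1] == 2048 and len(w) >= 10


class TestHurstGrid:
    def test_grid_matches_per_series_estimates(self, random_stack):
        hg = hurst_grid(random_stack)
        r, c = 3, 5
        h_single = estimate_hurst(random_stack.values[:, r, c])
        assert hg.H[r, c] == pytest.approx(h_single, rel=1e-12)

    def test_masked_pixels_nan(self, masked_stack):
        # 10-year series: windows {4, 5, 10}
        hg = hurst_grid(masked_stack)
        assert np.isnan(hg.H[0, 0])


class TestClassifyHurst:
    @pytest.mark.parametrize(
        "H, expected",
        [(0.5, "random"), (0.52, "random"), (0.3, "opposite"),
         (0.449, "opposite"), (0.551, "continuous"), (0.9, "continuous")],
    )
    def test_band_scheme(self, H, expected):
        hg = classify_hurst(np.array([[H]]), band=0.05)
        assert H_CLASSES[int(hg.h_class[0, 0])] == expected


class TestClassifyFuture:
    @pytest.mark.parametrize(
        "h_name, slope, p, expected",
        [
            ("continuous", 0.1, 0.01, "continuous_significant_increase"),
            ("continuous", 0.1, 0.2, "continuous_increase"),
            ("continuous", -0.1, 0.01, "continuous_significant_decrease"),
            ("continuous", -0.1, 0.2, "continuous_decrease"),
            ("opposite", 0.1, 0.9, "improvement_to_degradation"),
            ("opposite", -0.1, 0.001, "degradation_to_improvement"),
            ("random", 0.1, 0.001, "random_fluctuation"),
        ],
    )
    def test_scheme(self, h_name, slope, p, expected):
        h_val = {"opposite": 0.3, "random": 0.5, "continuous": 0.8}[h_name]
        hg = classify_hurst(np.array([[h_val]]))
        hg, _ = classify_future(hg, np.array([[slope]]), np.array([[p]]))
        assert FUTURE_CLASSES[int(hg.future_class[0, 0])] == expected

    def test_exhaustive_truth_table(self):
        """Every (H class, slope sign, significance) combination maps to
        exactly one of the seven classes, and all seven are reachable."""
        h_vals = {"opposite": 0.2, "random": 0.5, "continuous": 0.8}
        seen = set()
        for h_name, s, p in itertools.product(h_vals, [-0.1, 0.0, 0.1], [0.01, 0.5]):
            hg = classify_hurst(np.array([[h_vals[h_name]]]))
            hg, _ = classify_future(hg, np.array([[s]]), np.array([[p]]))
            code = int(hg.future_class[0, 0])
            assert code in FUTURE_CLASSES, (h_name, s, p)
            seen.add(code)
        assert seen == set(FUTURE_CLASSES)

    def test_zero_slope_tie_break_to_decrease_side(self):
        hg = classify_hurst(np.array([[0.8]]))
        hg, _ = classify_future(hg, np.array([[0.0]]), np.array([[0.5]]))
        assert FUTURE_CLASSES[int(hg.future_class[0, 0])] == "continuous_decrease"

    def test_fractions_sum_to_one_and_group_labels(self, rng):
        H = rng.uniform(0.1, 0.95, size=(40, 40))
        hg = classify_hurst(H)
        slopes = rng.normal(0, 0.01, size=(40, 40))
        ps = rng.random((40, 40))
        hg, frac = classify_future(hg, slopes, ps)
        assert frac["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert set(frac["group"]) == {"random", "improvement", "degradation"}
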