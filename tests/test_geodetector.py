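"""Geographical Detector statistics: q, interactions, risk, VIF, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vegdyn.geodetector import (
    INTERACTION_TYPES,
    StratifiedSample,
    classify_interaction,
    discretize,
    factor_q,
    interaction_q,
    risk_detect,
    vif_screen,
)


def brute_q(y, codes):
    """Independent sums-of-squares oracle: q = 1 - SSW/SST."""
    y = np.asarray(y, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    ssw = 0.0
    for lv in np.unique(codes):
        g = y[codes == lv]
        ssw += ((g - g.mean()) ** 2).sum()
    return 1.0 - ssw / sst


def sample_of(y, codes, name="f"):
    return StratifiedSample(y=np.asarray(y, float), strata={name: np.asarray(codes)})


class TestFactorQ:
    def test_worked_example(self):
        """y=(1,2,3,10,11,12) with strata AAA/BBB: SSW=4, SST=125.5."""
        q, _ = factor_q(sample_of([1, 2, 3, 10, 11, 12], [1, 1, 1, 2, 2, 2]), "f")
        assert q == pytest.approx(1 - 4 / 125.5, rel=1e-12)
        assert q == pytest.approx(0.9681, abs=1e-4)

    def test_within_constant_distinct_means_q_one(self):
        q, _ = factor_q(sample_of([2, 2, 5, 5, 9, 9], [1, 1, 2, 2, 3, 3]), "f")
        assert q == pytest.approx(1.0, abs=1e-14)

    def test_single_stratum_q_zero(self, rng):
        q, p = factor_q(sample_of(rng.normal(size=20), np.ones(20, int)), "f")
        assert q == 0.0 and p == 1.0

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(50):
            n = rng.integers(10, 60)
            codes = rng.integers(1, 5, size=n)
            if np.bincount(codes).max() < 2 or np.unique(codes).size < 2:
                continue
            y = rng.normal(size=n)
            try:
                q, _ = factor_q(sample_of(y, codes), "f", permutations=9)
            except ValueError:
                continue
            assert q == pytest.approx(brute_q(y, codes), rel=1e-12, abs=1e-14)

    def test_relabeling_and_affine_invariance(self, rng):
        y = rng.normal(size=40)
        codes = rng.integers(1, 4, size=40)
        q0, _ = factor_q(sample_of(y, codes), "f", permutations=9)
        q1, _ = factor_q(sample_of(y, codes * 7 + 3), "f", permutations=9)
        q2, _ = factor_q(sample_of(y * 2.5 + 1.0, codes), "f", permutations=9)
        assert q1 == pytest.approx(q0, rel=1e-12)
        assert q2 == pytest.approx(q0, rel=1e-12)
        assert 0.0 <= q0 <= 1.0

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            factor_q(sample_of(np.ones(10), [1] * 5 + [2] * 5), "f")

    def test_singleton_level_rejected(self):
        with pytest.raises(ValueError, match=">= 2 members"):
            factor_q(sample_of([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 2]), "f")

    def test_ncf_p_small_for_strong_separation(self):
        q, p = factor_q(
            sample_of([1, 2, 3, 10, 11, 12], [1, 1, 1, 2, 2, 2]), "f", method="ncf"
        )
        assert q == pytest.approx(1 - 4 / 125.5, rel=1e-12)
        assert p < 0.05

    def test_permutation_p_detects_planted_structure(self, rng):
        codes = np.repeat([1, 2], 50)
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        _, p = factor_q(sample_of(y, codes), "f", permutations=199, seed=0)
        assert p <= 0.01


class TestRefinementMonotonicity:
    def test_refining_never_decreases_q(self, rng):
        for _ in range(30):
            n = 80
            coarse = rng.integers(1, 4, size=n)
            # refine each coarse level into up to 2 sublevels
            fine = coarse * 10 + rng.integers(0, 2, size=n)
            y = rng.normal(size=n)
            assert brute_q(y, fine) >= brute_q(y, coarse) - 1e-12

    def test_interaction_with_refining_factor_equals_finer_q(self, rng):
        n = 200
        coarse = rng.integers(1, 3, size=n)
        fine = coarse * 10 + rng.integers(0, 3, size=n)
        y = rng.normal(size=n) + 0.5 * fine
        s = StratifiedSample(y=y, strata={"a": coarse, "b": fine})
        out = interaction_q(s, "a", "b")
        assert out["q_ab"] == pytest.approx(out["q_b"], rel=1e-12)


class TestInteractionTypes:
    @pytest.mark.parametrize(
        "qa, qb, qab, expected",
        [
            (0.2, 0.1, 0.35, "enhance_nonlinear"),
            (0.2, 0.1, 0.25, "enhance_bivariate"),
            (0.2, 0.1, 0.30, "independent"),
            (0.2, 0.1, 0.15, "weaken_univariate"),
            (0.2, 0.1, 0.05, "weaken_nonlinear"),
        ],
    )
    def test_taxonomy(self, qa, qb, qab, expected):
        assert classify_interaction(qa, qb, qab) == expected
        assert expected in INTERACTION_TYPES

    def test_cross_classification_q_matches_brute_force(self, rng):
        n = 300
        a = rng.integers(1, 4, size=n)
        b = rng.integers(1, 3, size=n)
        y = rng.normal(size=n) + a + 0.5 * b
        s = StratifiedSample(y=y, strata={"a": a, "b": b})
        out = interaction_q(s, "a", "b")
        pair = a * 100 + b
        if out["merged_cells"] == 0:
            assert out["q_ab"] == pytest.approx(brute_q(y, pair), rel=1e-12)
        assert out["q_ab"] >= max(out["q_a"], out["q_b"]) - 1e-9


class TestRiskDetector:
    def test_identical_levels_not_significant(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        out = risk_detect(sample_of(y, [1, 1, 1, 2, 2, 2]), "f")
        assert out["t_matrix"][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert not out["significant"][0, 1]

    def test_matches_welch_oracle(self, rng):
        g1 = rng.normal(0, 1, 100)
        g2 = rng.normal(1, 1, 100)
        y = np.concatenate([g1, g2])
        codes = np.repeat([1, 2], 100)
        out = risk_detect(sample_of(y, codes), "f")
        t_ref, p_ref = stats.ttest_ind(g1, g2, equal_var=False)
        assert out["t_matrix"][0, 1] == pytest.approx(t_ref, rel=1e-12)
        assert out["significant"][0, 1] == (p_ref <= 0.05)

    def test_most_favorable_is_planted_max_mean(self, rng):
        y = np.concatenate([
            rng.normal(0.0, 0.1, 30),
            rng.normal(5.0, 0.1, 30),
            rng.normal(2.0, 0.1, 30),
        ])
        codes = np.repeat([1, 2, 3], 30)
        out = risk_detect(sample_of(y, codes), "f")
        assert out["most_favorable_code"] == 2

    def test_singleton_level_excluded_with_warning(self, rng):
        y = np.concatenate([rng.normal(size=10), rng.normal(size=10), [99.0]])
        codes = np.array([1] * 10 + [2] * 10 + [3])
        with pytest.warns(UserWarning, match="singleton"):
            out = risk_detect(sample_of(y, codes), "f")
        assert 3 not in out["table"]["level_code"].to_numpy()


class TestDiscretize:
    def test_equal_interval_breaks(self):
        x = np.arange(0.0, 8.0, 0.5)
        codes = discretize(x, "equal_interval", k=4)
        # breaks 0, 1.875, 3.75, 5.625, 7.5
        assert codes.min() == 1 and codes.max() == 4
        assert (np.diff(codes) >= 0).all()

    def test_aspect_350_is_north(self):
        codes = discretize(np.array([350.0, 10.0, 45.0, 180.0]), "circular_aspect")
        assert codes[0] == 1 and codes[1] == 1  # north wraps 337.5 -> 22.5
        assert codes[2] == 2                    # northeast
        assert codes[3] == 5                    # south

    def test_quantile_equal_counts(self, rng):
        x = rng.uniform(size=100)
        codes = discretize(x, "quantile", k=4)
        assert np.bincount(codes)[1:].tolist() == [25, 25, 25, 25]

    def test_custom_breaks_and_empty_bin_warning(self):
        x = np.array([0.1, 0.2, 0.9, 1.0])
        with pytest.warns(UserWarning, match="empty bin"):
            discretize(x, "custom_breaks", breaks=[0.0, 0.3, 0.6, 1.1])

    def test_nan_maps_to_zero(self):
        codes = discretize(np.array([np.nan, 1.0, 2.0, 3.0]), "equal_interval", k=2)
        assert codes[0] == 0


class TestVifScreen:
    def test_orthogonal_columns_all_retained(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({
            "a": np.sin(2 * np.pi * t / n),
            "b": np.cos(2 * np.pi * t / n),
            "c": np.sin(4 * np.pi * t / n),
        })
        kept, report = vif_screen(df)
        assert kept == ["a", "b", "c"]
        assert np.allclose(report["vif_initial"], 1.0, atol=1e-6)

    def test_duplicated_column_removed_as_infinite(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, report = vif_screen(df)
        assert len(kept) == 2 and "c" in kept
        assert np.isinf(report["vif_initial"][:2]).all()

    def test_boundary_vif_10_retained_under_strict_greater(self, rng):
        # construct x3 = (x1 + x2) + residual with R^2 a hair under 0.9,
        # i.e. VIF = 1 / (1 - R^2) at the 10.0 boundary
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        signal = x1 + x2
        X = np.stack([np.ones(n), x1, x2], axis=1)
        noise = rng.normal(size=n)
        noise_perp = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        sc = signal - signal.mean()
        c = np.sqrt((sc @ sc) / (9.0 * (noise_perp @ noise_perp))) * (1 + 1e-6)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": signal + c * noise_perp})
        kept, report = vif_screen(df, threshold=10.0)
        vif3 = report.set_index("factor").loc["x3", "vif_initial"]
        assert vif3 == pytest.approx(10.0, rel=1e-4)
        assert "x3" in kept  # strictly greater than 10 is required to drop

    def test_too_few_factors_rejected(self):
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
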