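"""CSA extraction and agreement statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nerveseg.reliability import (CSAAgreement, bland_altman, csa_mm2,
                                  fisher_ci, icc_2_1,
                                  paired_difference_from_summary,
                                  paired_difference_inference,
                                  pearson_with_fisher_ci)


class TestCSA:
    def test_pixel_count_times_spacing_squared(self):
        mask = np.zeros((32, 32), bool)
        mask[:10, :10] = True
        assert csa_mm2(mask, 0.1) == pytest.approx(1.0)

    def test_largest_component_rule(self):
        mask = np.zeros((32, 32), bool)
        mask[:8, :10] = True  # 80 px
        mask[20:24, 20:25] = True  # 20 px
        assert csa_mm2(mask, 1.0, largest_component_only=True) == 80
        assert csa_mm2(mask, 1.0, largest_component_only=False) == 100

    def test_halving_spacing_quarters_area(self, rng):
        for _ in range(10):
            mask = rng.random((16, 16)) > 0.6
            assert csa_mm2(mask, 0.05, False) == pytest.approx(
                csa_mm2(mask, 0.1, False) / 4)

    def test_non_binary_raises(self):
        with pytest.raises(ValueError):
            csa_mm2(np.array([[0, 3]]), 0.1)


class TestPairedDifference:
    def test_recovers_printed_forearm_interval(self):
        r = paired_difference_from_summary(0.402, 0.696, 100)
        assert round(r.ci_low, 3) == 0.264
        assert round(r.ci_high, 3) == 0.540

    def test_recovers_printed_wrist_t_and_interval(self):
        r = paired_difference_from_summary(-0.168, 0.397, 77)
        assert round(abs(r.t_stat), 2) == 3.71
        assert round(r.ci_low, 3) == -0.258
        assert round(r.ci_high, 3) == -0.078

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            a = rng.normal(6, 2, n)
            b = a + rng.normal(0.3, 0.5, n)
            ours = paired_difference_inference(a, b)
            t, p = stats.ttest_rel(a, b)
            assert ours.t_stat == pytest.approx(t, rel=1e-10)
            assert ours.p_value == pytest.approx(p, rel=1e-10)

    def test_degenerate_spread_yields_undefined_t(self):
        r = paired_difference_inference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0.0
        assert np.isnan(r.t_stat)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_difference_inference([1.0], [1.0])
        with pytest.raises(ValueError):
            paired_difference_inference([1.0, 2.0], [1.0])


class TestPearsonFisher:
    def test_recovers_printed_interval(self):
        lo, hi = fisher_ci(0.879, 100)
        assert round(lo, 3) == 0.825
        assert round(hi, 3) == 0.917

    def test_perfect_correlation_guarded(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_with_fisher_ci(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lo == pytest.approx(1.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_null_interval_is_symmetric(self):
        lo, hi = fisher_ci(0.0, 5000)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_matches_scipy_r(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, _, _ = pearson_with_fisher_ci(x, y)
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, rel=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_with_fisher_ci(np.ones(10), np.arange(10.0))


def anova_icc_oracle(x):
    """ICC(2,1) via raw summation formulas (independent of the implementation)."""
    n, k = x.shape
    total = x.sum()
    correction = total**2 / (n * k)
    ss_total = (x**2).sum() - correction
    ss_rows = (x.sum(axis=1) ** 2).sum() / k - correction
    ss_cols = (x.sum(axis=0) ** 2).sum() / n - correction
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_give_unity(self):
        col = np.array([3.0, 5.0, 9.0, 2.0, 7.0, 4.0])
        icc, lo, hi = icc_2_1(np.column_stack([col, col]))
        assert icc == 1.0

    def test_toy_matrix_matches_summation_oracle(self):
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 8], [5, 6]], float)
        icc, _, _ = icc_2_1(x)
        assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-12)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            subj = rng.normal(0, 2, n)
            x = np.column_stack([subj + rng.normal(0, 1, n),
                                 subj + rng.normal(0.2, 1, n)])
            icc, _, _ = icc_2_1(x)
            assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-12)

    def test_recovers_variance_ratio(self):
        """Mean estimate over 500 replicates within 3 SE of sigma_s^2/(sigma_s^2+sigma_e^2)."""
        rng = np.random.default_rng(99)
        true_icc = 4.0 / (4.0 + 1.0)
        est = []
        for _ in range(500):
            subj = rng.normal(0, 2.0, 100)
            x = np.column_stack([subj + rng.normal(0, 1.0, 100),
                                 subj + rng.normal(0, 1.0, 100)])
            est.append(icc_2_1(x)[0])
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - true_icc) < 3 * se

    def test_monotone_in_method_noise(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(8, 2, 60)
        iccs = []
        for sigma in (2.0, 1.0, 0.25):
            x = np.column_stack([subj + rng.normal(0, sigma, 60),
                                 subj + rng.normal(0, sigma, 60)])
            iccs.append(icc_2_1(x)[0])
        assert iccs[0] < iccs[1] < iccs[2]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_2_1(np.zeros((3, 2)))
        bad = np.ones((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_2_1(bad)


class TestBlandAltman:
    def test_zero_differences(self):
        bias, lo, hi, frame = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)
        assert (frame["difference"] == 0).all()

    def test_hand_computed_limits(self):
        bias, lo, hi, _ = bland_altman([0.0, 2.0], [1.0, 1.0])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2), abs=1e-12)
        assert lo == pytest.approx(-1.96 * np.sqrt(2), abs=1e-12)

    def test_normal_coverage(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 1, 10_000)
        y = x + rng.normal(0.5, 0.3, 10_000)
        bias, lo, hi, frame = bland_altman(x, y)
        inside = ((frame["difference"] >= lo) & (frame["difference"] <= hi)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)


class TestAgreementModel:
    def test_fit_produces_consistent_results(self, rng):
        manual = rng.normal(9.8, 2.4, 60)
        predicted = manual + rng.normal(0.2, 0.5, 60)
        res = CSAAgreement(manual, predicted).fit()
        assert res.ci_low <= res.mean_diff <= res.ci_high
        assert res.ba_loa_low <= res.ba_bias <= res.ba_loa_high
        assert -1 <= res.pearson_r <= 1
        assert -1 <= res.icc21 <= 1
        assert res.ba_bias == pytest.approx(res.mean_diff)
        text = res.summary()
        assert "ICC(2,1)" in text and "Bland–Altman" in text

    def test_from_dataframe_and_json_round_trip(self, tmp_path, rng):
        manual = rng.normal(6, 1.5, 30)
        frame = pd.DataFrame({"manual_csa": manual,
                              "predicted_csa": manual + rng.normal(0, 0.4, 30)})
        res = CSAAgreement.from_dataframe(frame).fit()
        path = tmp_path / "agreement.json"
        res.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["n"] == 30
        assert loaded["icc21"] == pytest.approx(res.icc21)
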