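"""Exponential fitting, NOE, R1R2, CSP and trimmed-mean outlier calls."""

import numpy as np
import pandas as pd
import pytest

from allomif.errors import ParameterError
from allomif.relaxation import (
    T1_DELAYS_S,
    T1_REPLICATE_DELAYS_S,
    combined_csp,
    compute_noe,
    correlation_outliers,
    csp_table,
    fit_exponential_decay,
    fit_rates,
    r1r2_product,
    replicate_noise_sd,
    threshold_profile,
)
from allomif.synthetic import DecayCurveSpec, generate_decay_curves

from _oracles import brute_force_trim_flags


class TestExponentialFit:
    def test_noiseless_rate_recovered_to_machine_precision(self):
        t = T1_DELAYS_S
        y = 100.0 * np.exp(-2.0 * t)
        fit = fit_exponential_decay(t, y)
        assert fit.rate == pytest.approx(2.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(100.0, abs=1e-4)

    def test_constant_intensities_give_zero_rate(self):
        fit = fit_exponential_decay([0.0, 0.5, 1.0], [50.0, 50.0, 50.0])
        assert fit.rate == 0.0

    def test_negative_rate_flagged_not_clamped(self):
        t = np.array([0.0, 0.5, 1.0, 1.5])
        y = 10.0 * np.exp(0.8 * t)  # growing signal
        fit = fit_exponential_decay(t, y)
        assert fit.negative_rate
        assert fit.rate < 0

    def test_too_few_distinct_delays_rejected(self):
        with pytest.raises(ParameterError):
            fit_exponential_decay([0.0, 0.0, 1.0], [3.0, 3.1, 1.0])

    def test_replicate_noise_estimate_matches_generator(self):
        spec = DecayCurveSpec(
            true_rate=1.5, delays=T1_DELAYS_S,
            replicate_delays=T1_REPLICATE_DELAYS_S, noise_sd=0.02, seed=21,
        )
        table = generate_decay_curves(spec, n_residues=300)
        sigma = replicate_noise_sd(table)
        assert sigma == pytest.approx(2.0, rel=0.15)  # 2% of I0=100

    def test_monte_carlo_recovery_unbiased_with_calibrated_errors(self):
        spec = DecayCurveSpec(
            true_rate=1.2, delays=T1_DELAYS_S,
            replicate_delays=T1_REPLICATE_DELAYS_S, noise_sd=0.02, seed=22,
        )
        table = generate_decay_curves(spec, n_residues=200)
        fitted = fit_rates(table)
        bias = abs(fitted["rate"].mean() - 1.2) / 1.2
        coverage = (np.abs(fitted["rate"] - 1.2) < 3 * fitted["rate_err"]).mean()
        assert bias < 0.01
        assert coverage >= 0.99


class TestNOEandR1R2:
    def test_noe_ratios(self):
        assert compute_noe(0.8, 1.0) == pytest.approx(0.8)
        assert compute_noe(1.0, 1.0) == 1.0
        assert compute_noe(-0.2, 1.0) == pytest.approx(-0.2)

    def test_zero_reference_raises(self):
        with pytest.raises(ParameterError):
            compute_noe(0.5, 0.0)

    def test_product_and_propagated_uncertainty(self):
        rates = pd.DataFrame(
            {
                "residue": [1, 2, 3],
                "R1": [1.2, 1.0, 0.0],
                "R2": [10.0, 10.0, 8.0],
                "R1_err": [0.0, 0.1, 0.0],
                "R2_err": [0.0, 1.0, 0.0],
            }
        )
        out = r1r2_product(rates)
        assert out.loc[out["residue"] == 1, "R1R2"].iloc[0] == pytest.approx(12.0)
        assert out.loc[out["residue"] == 3, "R1R2"].iloc[0] == 0.0
        err = out.loc[out["residue"] == 2, "R1R2_err"].iloc[0]
        assert err == pytest.approx(np.sqrt((0.1 * 10) ** 2 + (1.0 * 1.0) ** 2), rel=1e-12)

    def test_missing_rate_skipped_and_reported(self):
        rates = pd.DataFrame(
            {"residue": [1, 2], "R1": [1.0, np.nan], "R2": [10.0, 9.0]}
        )
        out = r1r2_product(rates)
        assert out["residue"].tolist() == [1]
        assert out.attrs["skipped"] == [2]


class TestCSP:
    def test_identical_peaks_zero(self):
        assert combined_csp((8.2, 120.0), (8.2, 120.0)) == 0.0

    def test_hand_computed_value(self):
        # sqrt(0.05^2 + (0.14*0.5)^2) = 0.08602 ppm
        assert combined_csp((8.0, 120.0), (8.05, 120.5)) == pytest.approx(
            0.086023, abs=1e-5
        )

    def test_nitrogen_only_scales_linearly_with_weight(self):
        base = combined_csp((8.0, 120.0), (8.0, 121.0), nitrogen_weight=0.14)
        double = combined_csp((8.0, 120.0), (8.0, 121.0), nitrogen_weight=0.28)
        assert double == pytest.approx(2 * base, rel=1e-12)

    def test_missing_variant_peak_flagged_broadened(self):
        wt = pd.DataFrame(
            {"residue": [1, 2], "dH_ppm": [8.0, 8.5], "dN_ppm": [120.0, 118.0]}
        )
        var = pd.DataFrame({"residue": [1], "dH_ppm": [8.1], "dN_ppm": [120.0]})
        out = csp_table(wt, var)
        assert out.loc[out["residue"] == 2, "broadened"].iloc[0]
        assert np.isnan(out.loc[out["residue"] == 2, "csp_ppm"].iloc[0])


class TestThresholdProfile:
    def test_single_spike_is_flagged(self):
        profile = np.array([0.0] * 9 + [10.0])
        res = threshold_profile(profile)
        assert list(res.significant) == [9]

    def test_uniform_profile_flags_nothing(self):
        res = threshold_profile(np.full(20, 3.0))
        assert res.sigma == 0.0
        assert len(res.significant) == 0

    def test_translation_invariance_of_flag_set(self):
        rng = np.random.default_rng(31)
        profile = rng.exponential(0.05, 120)
        before = threshold_profile(profile).significant
        after = threshold_profile(profile + 7.5).significant
        np.testing.assert_array_equal(before, after)

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(32)
        for _ in range(200):
            profile = rng.normal(1.0, rng.uniform(0.1, 2.0), rng.integers(10, 150))
            res = threshold_profile(profile)
            tm, sd, flags = brute_force_trim_flags(profile)
            assert res.trimmed_mean == pytest.approx(tm, rel=1e-12)
            assert res.sigma == pytest.approx(sd, rel=1e-12)
            np.testing.assert_array_equal(res.significant, flags)

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            threshold_profile(np.arange(5.0))


class TestCorrelationOutliers:
    def _profiles(self, n=50, seed=41):
        rng = np.random.default_rng(seed)
        ref = pd.Series(rng.uniform(8, 20, n), index=range(1, n + 1))
        return ref

    def test_identical_profiles_rho_one_no_flags(self):
        ref = self._profiles()
        rep = correlation_outliers(ref, ref.copy())
        assert rep.rho == pytest.approx(1.0)
        assert rep.flagged == []

    def test_single_large_shift_is_the_only_flag(self):
        ref = self._profiles()
        var = ref + np.random.default_rng(42).normal(0, 0.05, len(ref))
        var.iloc[10] += 10.0
        rep = correlation_outliers(ref, var)
        assert rep.flagged == [ref.index[10]]

    def test_monotone_transform_keeps_rho_one(self):
        ref = self._profiles()
        rep = correlation_outliers(ref, ref**3)
        assert rep.rho == pytest.approx(1.0)
        assert np.any(rep.deviations != 0)

    def test_flag_set_invariant_under_residue_reordering(self):
        ref = self._profiles()
        var = ref.copy()
        var.iloc[5] += 8.0
        shuffled = np.random.default_rng(43).permutation(ref.index)
        rep_a = correlation_outliers(ref, var)
        rep_b = correlation_outliers(ref.loc[shuffled], var.loc[shuffled])
        assert set(rep_a.flagged) == set(rep_b.flagged)

    def test_perpendicular_axis_differs_by_sqrt2(self):
        ref = self._profiles()
        var = ref + 1.0
        plain = correlation_outliers(ref, var)
        perp = correlation_outliers(ref, var, perpendicular=True)
        np.testing.assert_allclose(
            perp.deviations, plain.deviations / np.sqrt(2.0), rtol=1e-12
        )

    def test_fewer_than_ten_common_residues_rejected(self):
        ref = pd.Series([1.0] * 5, index=range(5))
        with pytest.raises(ParameterError, match="common residues"):
            correlation_outliers(ref, ref)
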