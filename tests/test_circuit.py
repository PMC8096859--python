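"""Divider arithmetic, calibration inversion, loading, and the noise model."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import biodac as bd
from biodac.circuit import POT_MAX, POT_MIN


class TestAttenuationRatio:
    @pytest.mark.parametrize(
        "r1, rp, expected",
        [(1e6, 2000.0, 501.0), (1e7, 100.0, 100_001.0), (1e6, 100.0, 10_001.0)],
    )
    def test_printed_corner_values(self, r1, rp, expected):
        assert bd.attenuation_ratio(bd.DividerSetting(r1, rp)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invalid_coarse_rejected(self):
        with pytest.raises(bd.ConfigurationError):
            bd.DividerSetting(5e5, 1000.0)

    @pytest.mark.parametrize("rp", [50.0, 2500.0])
    def test_pot_out_of_range_rejected(self, rp):
        with pytest.raises(bd.ConfigurationError):
            bd.DividerSetting(1e6, rp)

    @given(
        rp1=st.floats(POT_MIN, POT_MAX - 1.0),
        delta=st.floats(0.5, 100.0),
    )
    @hyp_settings(derandomize=True, max_examples=50)
    def test_monotone_in_pot_and_coarse(self, rp1, delta):
        rp2 = min(rp1 + delta, POT_MAX)
        small_pot = bd.attenuation_ratio(bd.DividerSetting(1e6, rp1))
        large_pot = bd.attenuation_ratio(bd.DividerSetting(1e6, rp2))
        assert small_pot > large_pot  # decreasing in Rp
        big_coarse = bd.attenuation_ratio(bd.DividerSetting(1e7, rp1))
        assert big_coarse > small_pot  # increasing in R1


class TestDynamicRange:
    @pytest.mark.parametrize(
        "r1, rp, expected_vpp",
        [
            (1e6, 2000.0, 12.77e-3),
            (1e6, 100.0, 0.64e-3),
            (1e7, 2000.0, 1.28e-3),
            (1e7, 100.0, 64e-6),
        ],
    )
    def test_four_setting_corners(self, r1, rp, expected_vpp):
        vpp = bd.output_dynamic_range(bd.DividerSetting(r1, rp), 6.4)
        assert vpp == pytest.approx(expected_vpp, rel=5e-3)

    @given(
        r1=st.sampled_from([1e6, 1e7]),
        rp=st.floats(POT_MIN, POT_MAX),
        fullscale=st.floats(0.1, 10.0),
    )
    @hyp_settings(derandomize=True, max_examples=50)
    def test_range_times_ratio_conserves_fullscale(self, r1, rp, fullscale):
        setting = bd.DividerSetting(r1, rp)
        product = bd.output_dynamic_range(setting, fullscale) * bd.attenuation_ratio(
            setting
        )
        assert product == pytest.approx(fullscale, rel=1e-12)


class TestSettingsForTargetPeak:
    def test_max_analog_peak_maps_to_pot_max(self):
        setting, scale = bd.settings_for_target_peak(3.2 / 501.0)
        assert setting.coarse_resistance == 1e6
        assert setting.pot_resistance == pytest.approx(2000.0, rel=1e-9)
        assert scale == 1.0

    def test_min_analog_peak_maps_to_max_attenuation(self):
        setting, scale = bd.settings_for_target_peak(3.2 / 100_001.0)
        assert setting.coarse_resistance == 1e7
        assert setting.pot_resistance == pytest.approx(100.0, rel=1e-9)
        assert scale == 1.0

    def test_half_min_peak_needs_digital_scale_half(self):
        min_peak = 3.2 / 100_001.0
        setting, scale = bd.settings_for_target_peak(min_peak / 2.0)
        assert setting.pot_resistance == pytest.approx(100.0)
        assert scale == pytest.approx(0.5, rel=1e-12)

    def test_above_maximum_raises(self):
        with pytest.raises(bd.UnreachableTargetError):
            bd.settings_for_target_peak(0.01)  # 10 mV > 6.387 mV max

    @given(target=st.floats(1e-7, 6e-3))
    @hyp_settings(derandomize=True, max_examples=100)
    def test_forward_evaluation_round_trip(self, target):
        setting, scale = bd.settings_for_target_peak(target)
        peak = scale * 3.2 / bd.attenuation_ratio(setting)
        assert peak == pytest.approx(target, rel=1e-9)


class TestNoiseModel:
    def test_johnson_density_value(self):
        # sqrt(4 k T R) at 1 kOhm, 300 K
        assert bd.johnson_noise_density(1e3, 300.0) == pytest.approx(
            4.07e-9, rel=1e-3
        )

    def test_johnson_zero_resistance(self):
        assert bd.johnson_noise_density(0.0) == 0.0

    def test_johnson_sqrt_scaling(self):
        assert bd.johnson_noise_density(4e3, 300.0) == pytest.approx(
            2 * bd.johnson_noise_density(1e3, 300.0)
        )

    def test_johnson_negative_resistance_raises(self):
        with pytest.raises(bd.DomainError):
            bd.johnson_noise_density(-1.0)

    def test_opamp_noise_white_floor_and_corner(self):
        params = bd.NoiseModelParams()
        assert bd.opamp_voltage_noise_density(1e5, params) == pytest.approx(
            2.5e-9, rel=1e-4
        )
        assert bd.opamp_voltage_noise_density(2.0, params) == pytest.approx(
            2.5e-9 * np.sqrt(2), rel=1e-12
        )
        assert bd.opamp_voltage_noise_density(0.02, params) == pytest.approx(
            2.5e-9 * np.sqrt(101), rel=1e-12
        )

    def test_opamp_noise_rejects_nonpositive_frequency(self):
        with pytest.raises(bd.DomainError):
            bd.opamp_voltage_noise_density(0.0)

    def test_total_density_degenerate_cases(self, worst_case_setting):
        tiny = 1e-30  # params must be positive; this is numerically zero
        only_johnson = bd.NoiseModelParams(
            opamp_voltage_noise_white=tiny, opamp_current_noise=tiny
        )
        rs = worst_case_setting.source_resistance
        assert bd.total_output_noise_density(
            worst_case_setting, 1e3, only_johnson
        ) == pytest.approx(bd.johnson_noise_density(rs, 300.0), rel=1e-9)

    def test_voltage_noise_dominates_current_noise_in_pot_range(self):
        # across the usable pot range the op-amp voltage noise exceeds the
        # current-noise contribution, the basis for the op-amp choice
        params = bd.NoiseModelParams()
        for rp in (100.0, 500.0, 1000.0, 2000.0):
            rs = bd.DividerSetting(1e6, rp).source_resistance
            e_i = params.opamp_current_noise * rs
            e_v = bd.opamp_voltage_noise_density(1e3, params)
            assert e_v > e_i


class TestCumulativeRmsNoise:
    def test_worst_case_below_amplifier_floor(self, worst_case_setting):
        rms = bd.cumulative_rms_noise(worst_case_setting, 0.1, 1e4)
        assert rms < 2.4e-6

    def test_zero_width_band(self, worst_case_setting):
        assert bd.cumulative_rms_noise(worst_case_setting, 10.0, 10.0) == 0.0

    def test_inverted_band_raises(self, worst_case_setting):
        with pytest.raises(bd.DomainError):
            bd.cumulative_rms_noise(worst_case_setting, 100.0, 10.0)

    def test_white_noise_closed_form(self, worst_case_setting):
        # with flicker corner numerically zero and fixed densities, the
        # integral must reduce to e * sqrt(bandwidth)
        params = bd.NoiseModelParams(
            temperature=1e-30, opamp_voltage_noise_white=2.5e-9,
            opamp_current_noise=1e-30, flicker_corner=1e-30,
        )
        rms = bd.cumulative_rms_noise(worst_case_setting, 10.0, 1010.0, params)
        assert rms == pytest.approx(2.5e-9 * np.sqrt(1000.0), rel=1e-4)

    def test_quadrature_additivity_over_disjoint_bands(self, worst_case_setting):
        a = bd.cumulative_rms_noise(worst_case_setting, 0.1, 50.0)
        b = bd.cumulative_rms_noise(worst_case_setting, 50.0, 1e4)
        total = bd.cumulative_rms_noise(worst_case_setting, 0.1, 1e4)
        assert a**2 + b**2 == pytest.approx(total**2, rel=1e-6)

    def test_monotone_in_band_high(self, worst_case_setting):
        values = [
            bd.cumulative_rms_noise(worst_case_setting, 0.1, hi)
            for hi in (1.0, 10.0, 100.0, 1e3, 1e4)
        ]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestNoiseBudget:
    def test_total_is_quadrature_sum_and_rms_monotone(self, worst_case_setting):
        budget = bd.noise_budget(worst_case_setting)
        quad = np.sqrt(
            budget.johnson_density**2
            + budget.opamp_voltage_density**2
            + budget.opamp_current_density**2
        )
        np.testing.assert_allclose(budget.total_density, quad, rtol=1e-12)
        assert np.all(np.diff(budget.cumulative_rms) >= 0)

    def test_budget_endpoint_matches_scalar_integral(self, worst_case_setting):
        budget = bd.noise_budget(worst_case_setting, 0.1, 1e4)
        scalar = bd.cumulative_rms_noise(worst_case_setting, 0.1, 1e4)
        assert budget.cumulative_rms[-1] == pytest.approx(scalar, rel=1e-6)

    def test_export_round_trip(self, worst_case_setting, tmp_path):
        budget = bd.noise_budget(worst_case_setting, points=200)
        path = tmp_path / "budget.tsv"
        budget.save(path)
        table = np.loadtxt(path)
        np.testing.assert_allclose(table, budget.to_table(), rtol=1e-6)


class TestLoadedOutput:
    def test_infinite_load_unbuffered_is_open_circuit(self):
        setting = bd.DividerSetting(1e6, 2000.0, buffered=False)
        assert bd.loaded_output_voltage(setting, 1.0, np.inf) == 1.0

    def test_matched_load_halves_voltage(self):
        setting = bd.DividerSetting(1e6, 2000.0, buffered=False)
        z_out = setting.source_resistance
        assert bd.loaded_output_voltage(setting, 1.0, z_out) == pytest.approx(0.5)

    def test_buffer_is_load_independent(self):
        setting = bd.DividerSetting(1e6, 2000.0, buffered=True)
        for z in (10.0, 1e3, 1e6):
            assert bd.loaded_output_voltage(setting, 1.0, z) == 1.0

    def test_buffered_beats_unbuffered_for_finite_load(self):
        buf = bd.DividerSetting(1e7, 100.0, buffered=True)
        unbuf = bd.DividerSetting(1e7, 100.0, buffered=False)
        for z in (10.0, 1e3, 1e5):
            assert bd.loaded_output_voltage(buf, 1.0, z) > bd.loaded_output_voltage(
                unbuf, 1.0, z
            )

    def test_nonpositive_load_raises(self):
        setting = bd.DividerSetting(1e6, 2000.0, buffered=False)
        with pytest.raises(bd.DomainError):
            bd.loaded_output_voltage(setting, 1.0, 0.0)


def test_setting_json_round_trip(tmp_path):
    from biodac.circuit import load_setting, save_setting

    setting = bd.DividerSetting(1e7, 314.0, buffered=False)
    path = tmp_path / "setting.json"
    save_setting(setting, path)
    assert load_setting(path) == setting
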