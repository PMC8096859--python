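"""Divider settings and output dynamic range.

Shows how the coarse resistor + potentiometer divider maps the converter's
6.4 Vpp full scale onto physiological amplitudes, and how a target peak is
inverted back to a setting.
"""

import biodac as bd

print("Attenuation ratio and output span at the four setting corners")
for r1, rp in [(1e6, 2000.0), (1e6, 100.0), (1e7, 2000.0), (1e7, 100.0)]:
    setting = bd.DividerSetting(r1, rp)
    ratio = bd.attenuation_ratio(setting)
    vpp = bd.output_dynamic_range(setting, 6.4)
    print(f"  R1={r1 / 1e6:>4.0f} MOhm  Rp={rp:>6.0f} Ohm  "
          f"ratio {ratio:>9.0f}:1  span {vpp * 1e3:8.3f} mVpp")

print("\nCalibrating so the DAC maximum reproduces a 50 uV LFP extremum:")
setting, scale = bd.settings_for_target_peak(50e-6)
print(f"  -> coarse {setting.coarse_resistance / 1e6:.0f} MOhm, "
      f"pot {setting.pot_resistance:.1f} Ohm, digital scale {scale:g}")
print(f"  forward check: {scale * 3.2 / bd.attenuation_ratio(setting) * 1e6:.3f} uV")

print("\nBelow the 32 uV analog floor, digital scaling takes over:")
setting, scale = bd.settings_for_target_peak(10e-6)
print(f"  -> pot at {setting.pot_resistance:.0f} Ohm (max attenuation), "
      f"digital scale {scale:.3f}")
print("A digital scale < 1 trades dynamic range for amplitude: the 24-bit")
print("converter then spans only that fraction of its code space.")
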