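"""Prepare a biosignal, replay it through the noisy simulated chain, and
score the re-recording against the original.

The pipeline mirrors bench practice: zero-phase DC removal, upsampling to
the DAC rate, extremum normalization, per-signal calibration, playback
through the quantizer + AC coupling + divider with circuit noise, then
"acquisition" at 30 kSPS with an amplifier noise floor, downsampling back,
cross-correlation alignment, and correlation/RMSE metrics.
"""

import biodac as bd

# surrogate LFP: 20 Hz bursts stepping 50 -> 10 uV (volts for the pipeline)
lfp = bd.lfp_burst_waveform()
signal = lfp.with_samples(lfp.samples * 1e-6, units="V")

dac = bd.DacSpec(sample_rate=48_000.0)
normalized, plan = bd.prepare_for_playback(signal, dac=dac)
print(f"Signal extremum: {plan.signal_peak * 1e6:.2f} uV")
print(f"Calibration: coarse {plan.setting.coarse_resistance / 1e6:.0f} MOhm, "
      f"pot {plan.setting.pot_resistance:.1f} Ohm, "
      f"digital scale {plan.digital_scale:g}")

recorded = bd.simulate_chain(
    normalized, dac=dac, setting=plan.setting,
    digital_scale=plan.digital_scale, noise_on=True, seed=42,
)
back = bd.resample_to_dac(recorded, signal.sample_rate)
fid = bd.fidelity_metrics(signal, back)
print(f"\nRe-recorded vs original after alignment (lag {fid.lag} samples):")
print(f"  correlation r = {fid.correlation:.4f}")
print(f"  RMSE          = {fid.rmse * 1e6:.3f} uV")
print("An r near 1 with sub-uV RMSE means the chain reproduces the waveform")
print("shape faithfully; the residual is the simulated circuit + amplifier")
print("noise plus the AC-coupling phase shift at 20 Hz.")
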