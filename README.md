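# biodac

**Simulator and bench-protocol toolkit for audio-DAC biosignal playback.**

Closed-loop biomedical devices — adaptive deep-brain stimulators, seizure
detectors, artifact-rejection front ends — need to be tested against
realistic electrophysiological inputs long before they meet a patient. A
practical way to deliver those inputs is a *biosignal waveform generator*: a
multichannel 24-bit audio DAC whose line-level output is scaled down to
physiological amplitudes (tens of microvolts to millivolts) by a resistive
attenuation and buffering circuit, driven by ordinary audio streaming from a
host computer.

`biodac` implements that whole paradigm in software, for instrumentation
engineers and neural-engineering labs who want to design, budget, and
validate such a playback rig — or prototype the analysis pipelines around
one — without hardware on the bench:

- **Circuit model** — divider attenuation `(R1 + Rp)/Rp` spanning 501:1 to
  100 001:1, output dynamic range, calibration inversion (target peak →
  setting + digital scale), load-dependent output, and the full theoretical
  noise budget: Johnson noise `√(4kTR_s)` of the source resistance
  `R_s = R1 ∥ Rp`, op-amp voltage noise `e_n√(1 + f_c/f)` with its 1/f
  corner, current noise `i_n R_s`, all summed in quadrature and integrated
  over a band to a cumulative RMS figure.
- **DAC model** — symmetric mid-tread 24-bit quantization, code→volts
  mapping at the 6.4 Vpp full scale, and the load-dependent first-order
  AC-coupling high-pass (1 Hz datasheet corner; 0.57 Hz measured preset).
- **Signal preparation** — zero-phase Butterworth DC removal, polyphase
  resampling to the DAC rate, extremum normalization, and three calibration
  strategies (fixed, per-signal, hybrid).
- **Chain simulator** — quantize → convert → AC-couple → attenuate → load →
  circuit noise → re-record through an acquisition front-end model
  (band-pass, 30 kSPS, 2.4 μVrms floor, ±5 mV range), seeded and
  reproducible.
- **Bench protocols** — Bartlett averaged-periodogram noise density, ramp
  linearity with slope-normalized residuals, 40-tone swept-sine frequency
  response with fixed-frequency sine fits, an R² ≥ 0.95 quality gate and
  −3 dB interpolation, and cross-correlation-aligned fidelity metrics
  (Pearson r, RMSE).
- **Synthetic biosignals** — amplitude-modulated beta-band LFP bursts,
  130 Hz stimulation-artifact trains, tones, ramps, white and pink noise.
- **Closed-loop detector** — beta band power (16.6–26.37 Hz) in 100 ms
  windows plus a dual-threshold hysteresis state machine and a
  rate-limited stimulation-current trace.

## Worked example

Replay a surrogate local-field-potential recording through the simulated
chain and score the re-recording (`examples/playback_fidelity.py`):

```python
import biodac as bd

lfp = bd.lfp_burst_waveform()                       # 30 s, 20 Hz bursts, uV
signal = lfp.with_samples(lfp.samples * 1e-6, units="V")

dac = bd.DacSpec(sample_rate=48_000.0)
normalized, plan = bd.prepare_for_playback(signal, dac=dac)
recorded = bd.simulate_chain(normalized, dac=dac, setting=plan.setting,
                             digital_scale=plan.digital_scale,
                             noise_on=True, seed=42)
back = bd.resample_to_dac(recorded, signal.sample_rate)
fid = bd.fidelity_metrics(signal, back)
```

which prints

```
Signal extremum: 50.33 uV
Calibration: coarse 10 MOhm, pot 157.3 Ohm, digital scale 1
Re-recorded vs original after alignment (lag 0 samples):
  correlation r = 0.9979
  RMSE          = 0.955 uV
```

The calibration step inverted the divider formula so the converter's 3.2 V
peak lands exactly on the 50 μV signal extremum; after the full noisy loop
the waveform comes back with r ≈ 0.998 and the residual is dominated by the
simulated circuit and amplifier noise. The other scripts in `examples/`
cover the dynamic-range arithmetic, the noise budget, the swept-tone
frequency response, closed-loop burst detection and buffered streaming, each
printing and explaining its numbers.

A thin CLI wraps the same calls: `biodac generate|prepare|simulate|
characterize|detect|play --help`.

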