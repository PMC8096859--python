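# Methods

This note documents the models behind `biodac`, the defaults they ship
with, and what the simulated results do and do not say about physical
hardware.

## The playback chain

The system being modeled is a biosignal waveform generator built from an
8-channel, 24-bit audio DAC followed, per channel, by a passive voltage
divider and an optional unity-gain buffer. The simulator composes five
stages, each individually exposed:

1. **Quantization.** Normalized samples in [−1, 1] map to signed mid-tread
   PCM codes in `[−2^(b−1), 2^(b−1)−1]`, rounding to nearest with ties away
   from zero. Out-of-range samples saturate (with a logged count) rather
   than raise, matching converter behavior. The code→volts map is linear
   with the maximum code at +fullscale/2 (6.4 Vpp default), so the code
   span end-to-end covers one LSB more than the nominal span — the standard
   PCM asymmetry.
2. **AC coupling.** A causal single-pole Butterworth high-pass models the
   converter's output coupling. The corner is load dependent; the default
   is the 1 Hz datasheet value for a 47 kΩ load, with the bench-measured
   0.57 Hz available as `MEASURED_HIGHPASS_CORNER`. An optional
   reconstruction low-pass (off by default, since every protocol here stays
   below 10 kHz) stands in for the converter's sample-rate-dependent output
   filter, whose family the datasheet does not specify.
3. **Attenuation.** `ratio = (R1 + Rp)/Rp` with R1 ∈ {1 MΩ, 10 MΩ} and
   Rp ∈ [100 Ω, 2 kΩ] (the pot is linear-taper, continuous, and never
   operated below 100 Ω). The achievable ratio range is exactly
   [501, 100 001], i.e. 12.77 mVpp down to 64 μVpp from a 6.4 Vpp source.
   Calibration inverts this: `Rp = R1/(ratio − 1)`, preferring the 1 MΩ
   branch when both reach the target, and falling back to digital scaling
   only below the 32 μV analog floor.
4. **Loading.** A buffered channel is an ideal unity-gain buffer (the
   10⁷-fold load margin of the real part justifies ignoring gain error);
   unbuffered, the output impedance `Z_out = R1 ∥ Rp ≈ 2 kΩ` forms a
   further divider with the load. Buffer input loading of the divider is
   assumed negligible.
5. **Acquisition.** Re-recording is modeled as a causal first-order
   high-pass plus third-order low-pass Butterworth band-pass (the real
   amplifier's topology is not public), saturation at ±5 mV, polyphase
   resampling to 30 kSPS, and additive white Gaussian noise at a 2.4 μVrms
   floor. Defaults follow a typical electrophysiology front end; a
   0.09 Hz–20.5 kHz wideband preset exists.

## Noise model

Three output-referred sources are summed in quadrature:

- Johnson noise `√(4 k T R_s)` of the divider's parallel (source)
  resistance `R_s = R1 ∥ Rp`; temperature defaults to 300 K and is a
  parameter.
- Op-amp input voltage noise `e_n √(1 + f_c/f)`: the standard
  single-corner flicker form with the white floor `e_n = 2.5 nV/√Hz` and
  corner `f_c = 2 Hz` of a low-voltage-noise bipolar buffer.
- Op-amp current noise `i_n = 0.4 pA/√Hz` converted through `R_s`. Only
  the voltage noise carries a 1/f corner; the current-noise corner is not
  published for the modeled part and is deliberately not guessed.

Band-integrated RMS noise is computed by the trapezoidal rule on a
log-spaced grid (4000 points per band by default; ≥ 1000 keeps the
closed-form white-noise check well inside 0.1%), which resolves the 1/f
region across the five decades from 0.1 Hz to 10 kHz. At the worst-case pot
setting (2 kΩ) this integral evaluates to ≈ 0.63 μVrms over 0.1 Hz–10 kHz —
comfortably below the 2.4 μVrms floor of the reference acquisition
amplifier, which is the design's headline noise comparison. Component
tolerances, op-amp bandwidth/slew limits, and environmental or digital
switching noise are out of scope; a physical build will measure a higher
floor than this theoretical budget.

In the chain simulator the circuit noise is injected as white Gaussian
noise whose per-sample variance equals the analytic cumulative power from
0.1 Hz to the simulation Nyquist. The 1/f excess below ~2 Hz is negligible
against that total; a config flag (`shape_flicker`) synthesizes the shaping
spectrally for studies that care about the lowest octaves.

## Signal preparation

DC removal uses a 3rd-order zero-phase (forward–backward) Butterworth
high-pass. The stated order is the design order; forward–backward
application doubles the effective magnitude order and cancels phase. The
default corner is 0.5 Hz — below the 0.57–1 Hz hardware coupling corner, so
the digital filter, not the hardware, sets the low-frequency edge. The
implementation pads by three filter time constants before filtering: the
scipy default pad is far too short for sub-hertz corners and leaves large
edge transients (this is visible as a ~50% spurious overshoot on burst-like
records if left at the default).

Resampling is polyphase with a Kaiser-windowed anti-aliasing filter and
reflection padding, after reducing the rate ratio to a rational factor.
Normalization scales by the most positive-or-negative sample and returns
that physical peak for calibration.

Calibration strategies: `per_signal` inverts the divider so the DAC maximum
lands on the signal extremum (best dynamic-range use); `fixed` validates
against a user-supplied setting and returns the digital scale needed;
`hybrid` keeps the pot at its 1 kΩ nominal value and picks only the coarse
switch — peak-to-peak above 1.28 mV selects the 1 MΩ branch, otherwise
10 MΩ, the split taken from the two branches' printed ranges.

## Bench protocols

- **Noise floor.** Recordings are concatenated and split into
  non-overlapping windows (1 s default; five 10 s records give the
  protocol's 50 windows); unmodified one-sided periodograms (boxcar, no
  overlap, no detrend) are averaged and reported as amplitude spectral
  density in V/√Hz. Parseval holds to the 1/√(#windows) sampling tolerance.
  RMS is computed per recording and summarized as mean ± SD.
- **Linearity.** The stimulus is ten 0.01 s full-span ramps separated by
  1 s of zeros; the 100:1 timescale separation against a 1 Hz coupling
  corner makes droop negligible (analytically bounded by
  `1 − exp(−2π f_c t) < 1%`). Ramps are located by activity-threshold edge
  detection (regions above 20% of peak, gaps shorter than a median region
  merged — the mid-ramp zero crossing must not split a ramp), averaged, fit
  with a least-squares line, and residuals divided by the fitted slope so
  they read in per-sample steps. How a real bench locates ramps is a free
  choice; edge detection was chosen over sync pulses to keep the stimulus
  minimal.
- **Frequency response.** 40 log-spaced tones, 0.1 Hz–10 kHz, each lasting
  5 of its own periods, each preceded by a 10 ms full-scale sync pulse and
  2 s of settling blank, and followed by a 2-periods blank (the protocol's
  blanking text is ambiguous between those two readings; both are config
  parameters). Each tone is fit with `A·sin(2πft + φ) + c` at fixed f —
  linear least squares on the sin/cos basis, which is the exact solution of
  the nonlinear problem once f is pinned. Fits with R² < 0.95 (about the
  mean, per the usual definition) are excluded. The first fitted period of
  each tone is discarded so causal-filter onset transients do not bias the
  amplitude. Magnitudes are referenced to the median passband (10–1000 Hz)
  amplitude; the −3 dB crossing is interpolated linearly in log-frequency,
  which on the 40-tone grid lands within ~1% of an analytic single-pole
  corner. Phase uncertainty is quoted as ±360·f/f_s degrees, the effect of
  a one-sample alignment error.
- **Fidelity.** The re-recording is downsampled to the original's rate,
  aligned at the cross-correlation peak, and scored with Pearson's r and
  RMSE on the aligned overlap (which must cover ≥ 50% of the original).

The frequency-response protocol, when run against the simulated chain in
tests and in the acceptance script, uses a 48 kSPS chain rate: within the
converter's supported range, comfortably above twice the highest tone, and
it keeps the ~350 s stimulus to a modest array size. The sweep is analyzed
on the playback output directly rather than through the acquisition model:
the acquisition high-pass at 0.09 Hz has a ~1.8 s time constant whose onset
transient would bias the 5-period tones near 1 Hz, confounding the corner
being measured.

## Synthetic signals

The LFP surrogate emulates pathological beta-band bursting: eight 1.5 s
long bursts starting at t = 0 with a 2 s interburst gap (8 × 3.5 s = 28 s
of content inside the 30 s record, trailing silence after), each long burst
five back-to-back 300 ms segments at 50/40/30/20/10 μV under a rectangular
envelope with the 20 Hz carrier phase-continuous across segments. The
generator is a pure function of its parameters — no noise, bit-identical
across runs. Rectangular envelopes (the source material says only
"decreasing amplitude") keep segment band powers exactly A²/2, which makes
the detector's threshold gap analytically known. The artifact train places
one-sample biphasic (charge-balanced) pulses at 130 Hz in 1 s-on/8 s-off
epochs. Pink noise is white Gaussian noise shaped by a 1/√f amplitude
filter and RMS-renormalized.

What these surrogates do *not* emulate: background neural broadband,
line-frequency interference, electrode drift, or the amplitude statistics
of real recordings. Passing the detection and fidelity tests therefore
demonstrates that the algorithms are correct on their design conditions,
not that a specific device will hit the same numbers on patient data.

## Detector

Band power is computed by a 4th-order zero-phase Butterworth band-pass
(16.6–26.37 Hz default) followed by mean-squared amplitude over
non-overlapping 100 ms windows. The dual-threshold machine enters the high
state when power is at or above the onset threshold (sustained for an
optional hold time, default 0 — immediate onset), and exits below the
offset threshold; offset ≤ onset is enforced, which guarantees strictly
alternating transitions on monotone power ramps. The window precondition
requires at least two cycles of the band's upper edge per window.
The implanted device this emulates runs a proprietary linear-discriminant
detector; band power + hysteresis is a deliberate, documented
simplification that reproduces the on/off behavior, not the discriminant.
The stimulation trace slews toward each state's target current at a fixed
mA/s rate (defaults 0 → 2 mA at 4 mA/s, chosen as representative; the real
device's mapping is not published).

## Numerical choices and degenerate inputs

- Integration tolerance: trapezoid on log grids, validated against the
  closed form `e·√Δf` for white noise.
- Quantizer ties round away from zero; the WAV writer uses the standard
  float→PCM scale of 2^(b−1) with the positive rail clipped, so integer
  round trips stay within 1 LSB.
- All-zero signals are rejected by normalization (degenerate input); empty
  quantizer input returns empty output; zero-width noise bands integrate
  to 0.
- Every stochastic path (circuit noise, acquisition noise, noise
  generators) takes an explicit integer seed; identical seeds give
  bit-identical outputs.
- 24-bit WAV is written via 3-byte little-endian packing; reads normalize
  scipy's high-byte-aligned int32 representation, so 24- and 32-bit files
  share one code path.

## Known limitations

- Harmonic distortion of the converter is not injected; the chain's only
  nonlinearity is quantization and explicit saturation.
- Electrode/electrolyte interfaces are reduced to a lumped load impedance.
- The acquisition model's filter topology is an assumption (1st-order HP +
  3rd-order LP); real amplifiers differ in the transition bands.
- Hardware-measured figures (bench noise floors, measured corner, saline
  amplitudes, per-biosignal fidelity on real devices) depend on physical
  setups and are outside what this simulator reproduces; the protocols are
  provided so users can produce those numbers on their own hardware.
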