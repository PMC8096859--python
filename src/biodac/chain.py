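"""End-to-end playback chain simulator.

Stands in for the hardware loop used on the bench: normalized digital
samples are quantized, converted to line-level volts, AC-coupled, attenuated
by the divider, optionally loaded, overlaid with the circuit's thermal/op-amp
noise, and finally "re-recorded" through a model of an electrophysiology
acquisition front end (band-pass, resampling, amplifier noise floor,
input-range clipping).

Circuit noise is injected as white Gaussian noise whose per-sample variance
equals the analytic cumulative noise power over the simulated bandwidth;
an optional flag adds the 1/f shaping below the flicker corner, whose power
contribution is negligible against the full band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .circuit import (
    DividerSetting,
    NoiseModelParams,
    attenuation_ratio,
    cumulative_rms_noise,
    loaded_output_voltage,
)
from .dac import DacSpec, codes_to_volts, dac_highpass, quantize, reconstruction_lowpass
from .errors import ConfigurationError
from .prep import resample_to_dac
from .waveform import Waveform

logger = logging.getLogger(__name__)

#: Lowest frequency included when converting the noise density to a
#: per-sample variance (the noise budget is conventionally integrated
#: upward from 0.1 Hz).
NOISE_BAND_LOW = 0.1


@dataclass(frozen=True)
class AcquisitionSpec:
    """Model of the recording front end used to capture the analog output.

    Defaults mirror a typical electrophysiology amplifier: 30 kSPS, a
    0.09 Hz–7.5 kHz band (a 0.09 Hz–20.5 kHz wideband option exists),
    2.4 μVrms noise floor, ±5 mV input range.
    """

    sample_rate: float = 30_000.0
    band: tuple[float, float] = (0.09, 7500.0)
    noise_floor: float = 2.4e-6          # Vrms
    input_range: float = 5e-3            # volts, symmetric

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigurationError("band must satisfy 0 < low < high")
        if hi >= self.sample_rate / 2 and lo >= self.sample_rate / 2:
            raise ConfigurationError("band lies entirely above Nyquist")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be non-negative")
        if not self.input_range > 0:
            raise ConfigurationError("input_range must be positive")


#: Wideband acquisition preset (maximum amplifier bandwidth).
WIDEBAND = AcquisitionSpec(band=(0.09, 20_500.0))


def simulate_playback(
    wave: Waveform,
    dac: DacSpec | None = None,
    setting: DividerSetting | None = None,
    digital_scale: float = 1.0,
    noise_on: bool = False,
    seed: int = 0,
    load_impedance: float = np.inf,
    noise_params: NoiseModelParams | None = None,
    shape_flicker: bool = False,
) -> Waveform:
    """Run normalized samples through the DAC + conditioning circuit.

    Parameters
    ----------
    wave
        Normalized signal in [-1, 1] at the DAC sample rate.
    digital_scale
        Multiplier applied to the samples before quantization (the digital
        part of a calibration plan).
    noise_on, seed
        When on, adds Gaussian noise at the circuit's predicted in-band RMS,
        reproducibly generated from ``seed``.
    load_impedance
        Finite values engage the loading model (only unbuffered settings
        are affected).
    shape_flicker
        Additionally shape the noise below the flicker corner as 1/f.

    Returns
    -------
    Waveform in volts at the DAC rate.
    """
    dac = dac or DacSpec()
    setting = setting or DividerSetting(1e6, 2000.0)
    if not (0 < digital_scale <= 1):
        raise ConfigurationError("digital_scale must lie in (0, 1]")
    if wave.peak() > 1.0 + 1e-12:
        raise ConfigurationError(
            "simulate_playback expects a normalized signal in [-1, 1]; "
            "run normalize_for_playback first"
        )
    if wave.sample_rate != dac.sample_rate:
        raise ConfigurationError(
            f"signal rate {wave.sample_rate} differs from DAC rate "
            f"{dac.sample_rate}; resample first"
        )

    codes = quantize(wave.samples * digital_scale, dac)
    volts = codes_to_volts(codes, dac)
    line = dac_highpass(Waveform(volts, dac.sample_rate, "V"), dac)
    line = reconstruction_lowpass(line, dac)
    out = line.samples / attenuation_ratio(setting)

    if np.isfinite(load_impedance):
        # linear network: scale by the per-volt loading factor
        factor = loaded_output_voltage(setting, 1.0, load_impedance)
        out = out * factor

    if noise_on:
        nyquist = dac.sample_rate / 2.0
        sigma = cumulative_rms_noise(setting, NOISE_BAND_LOW, nyquist,
                                     noise_params)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, size=len(out))
        if shape_flicker:
            noise = _shape_flicker(noise, dac.sample_rate,
                                   (noise_params or NoiseModelParams()).flicker_corner)
        out = out + noise

    return Waveform(out, dac.sample_rate, "V")


def _shape_flicker(noise: np.ndarray, fs: float, corner: float) -> np.ndarray:
    """Impose e(f) ∝ √(1 + f_c/f) shaping on white noise, preserving RMS."""
    n = len(noise)
    spectrum = np.fft.rfft(noise)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(f)
    nonzero = f > 0
    gain[nonzero] = np.sqrt(1.0 + corner / f[nonzero])
    gain[0] = 0.0  # no DC noise
    shaped = np.fft.irfft(spectrum * gain, n)
    rms_in = np.sqrt(np.mean(noise**2))
    rms_out = np.sqrt(np.mean(shaped**2))
    return shaped * (rms_in / rms_out) if rms_out > 0 else shaped


def simulate_acquisition(
    wave: Waveform,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
) -> Waveform:
    """Re-record an analog waveform through the acquisition front end.

    Applies the amplifier band-pass (first-order high-pass plus third-order
    low-pass Butterworth, both causal), saturates at the input range (with a
    logged clip count), resamples to the acquisition rate, and adds Gaussian
    noise at the configured floor.
    """
    acq = acq or AcquisitionSpec()
    x = wave.samples

    n_clip = int(np.count_nonzero(np.abs(x) > acq.input_range))
    if n_clip:
        logger.warning(
            "simulate_acquisition: %d sample(s) beyond the ±%g V input range "
            "saturated", n_clip, acq.input_range,
        )
        x = np.clip(x, -acq.input_range, acq.input_range)

    lo, hi = acq.band
    nyq_in = wave.sample_rate / 2.0
    if 0 < lo < nyq_in:
        sos = sps.butter(1, lo, btype="highpass", fs=wave.sample_rate,
                         output="sos")
        x = sps.sosfilt(sos, x)
    if hi < nyq_in:
        sos = sps.butter(3, hi, btype="lowpass", fs=wave.sample_rate,
                         output="sos")
        x = sps.sosfilt(sos, x)

    recorded = resample_to_dac(Waveform(x, wave.sample_rate, wave.units),
                               acq.sample_rate)

    if acq.noise_floor > 0:
        rng = np.random.default_rng(seed)
        recorded = recorded.with_samples(
            recorded.samples + rng.normal(0.0, acq.noise_floor,
                                          size=len(recorded))
        )
    return recorded


def simulate_chain(
    wave: Waveform,
    dac: DacSpec | None = None,
    setting: DividerSetting | None = None,
    acq: AcquisitionSpec | None = None,
    digital_scale: float = 1.0,
    noise_on: bool = True,
    seed: int = 0,
) -> Waveform:
    """Playback followed by acquisition — the full bench loop in one call.

    The seed is split deterministically between the two noise sources.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    play_seed = int(ss[0].generate_state(1)[0] % (2**31))
    acq_seed = int(ss[1].generate_state(1)[0] % (2**31))
    analog = simulate_playback(wave, dac, setting, digital_scale=digital_scale,
                               noise_on=noise_on, seed=play_seed)
    if acq is None:
        acq = AcquisitionSpec() if noise_on else AcquisitionSpec(noise_floor=0.0)
    elif not noise_on:
        acq = AcquisitionSpec(sample_rate=acq.sample_rate, band=acq.band,
                              noise_floor=0.0, input_range=acq.input_range)
    return simulate_acquisition(analog, acq, seed=acq_seed)
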