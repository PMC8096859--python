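"""Playback preparation: DC removal, resampling, normalization, calibration.

Before a stored biosignal can be replayed it is (1) high-pass filtered with a
zero-phase Butterworth to strip any DC offset — which would otherwise be
distorted by the converter's AC coupling — (2) resampled up to the DAC rate
for the best digital resolution, (3) normalized so its extremum sits at the
converter's full scale, and (4) matched to an analog divider setting so that
full scale reproduces the signal's physical peak.

Three calibration strategies are supported:

``per_signal``
    Re-calibrate for every signal: the divider is set so the DAC maximum
    maps exactly onto the signal extremum — best dynamic-range use.
``fixed``
    "Set it and forget it": a channel is calibrated once to a known maximum
    output; each signal is scaled digitally to fit under it.
``hybrid``
    The pot stays at its nominal value; only the coarse 1 MΩ / 10 MΩ switch
    is chosen from the signal size (peak-to-peak above 1.28 mV → large-signal
    branch), with residual digital scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .circuit import (
    COARSE_RESISTANCES,
    DividerSetting,
    attenuation_ratio,
    settings_for_target_peak,
)
from .dac import DacSpec
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    UnreachableTargetError,
)
from .waveform import Waveform

#: Nominal pot value used by the hybrid strategy, ohms.
NOMINAL_POT = 1000.0

#: Peak-to-peak threshold (volts) separating the large-signal (1 MΩ) and
#: small-signal (10 MΩ) hybrid branches.
HYBRID_LARGE_SIGNAL_VPP = 1.28e-3


@dataclass(frozen=True)
class CalibrationPlan:
    """How a prepared signal maps onto the hardware.

    ``digital_scale`` multiplies the normalized samples before streaming;
    it is 1 when analog attenuation alone reaches the target amplitude.
    ``reference_tone`` describes the sine played during manual pot trimming
    (frequency in Hz, expected output amplitude in volts).
    """

    strategy: str
    setting: DividerSetting
    digital_scale: float
    signal_peak: float                       # volts, the extremum calibrated to
    reference_tone: tuple[float, float] = (10.0, 0.0)

    def __post_init__(self):
        if not (0 < self.digital_scale <= 1):
            raise ConfigurationError("digital_scale must lie in (0, 1]")
        if self.strategy not in ("fixed", "per_signal", "hybrid"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "setting": self.setting.to_dict(),
            "digital_scale": self.digital_scale,
            "signal_peak_volts": self.signal_peak,
            "reference_tone_hz": self.reference_tone[0],
            "reference_tone_volts": self.reference_tone[1],
        }


def remove_dc(wave: Waveform, corner: float = 0.5, order: int = 3) -> Waveform:
    """Zero-phase Butterworth high-pass removing DC and drift.

    The stated ``order`` is the design order of the underlying filter; the
    zero-phase (forward–backward) application doubles the effective
    magnitude order and cancels phase distortion.  Default corner 0.5 Hz
    sits below the hardware AC-coupling corner so that the filter, not the
    hardware, decides the low-frequency cutoff.
    """
    nyquist = wave.sample_rate / 2.0
    if not (0 < corner < nyquist):
        raise ConfigurationError(
            f"corner must lie in (0, {nyquist}) Hz, got {corner}"
        )
    sos = sps.butter(order, corner, btype="highpass", fs=wave.sample_rate,
                     output="sos")
    # pad by ~3 filter time constants so edge transients of the low corner
    # do not leak into the record (the scipy default pad is far too short)
    padlen = min(len(wave) - 1, int(round(3.0 * wave.sample_rate / corner)))
    return wave.with_samples(sps.sosfiltfilt(sos, wave.samples, padlen=padlen))


def resample_to_dac(wave: Waveform, dac_rate: float) -> Waveform:
    """Anti-aliased rational-factor resampling to the DAC rate.

    Polyphase with a Kaiser-windowed filter; the record is reflection-padded
    so short records do not ring at the edges.  Same-rate input is returned
    unchanged.
    """
    if not dac_rate > 0:
        raise ConfigurationError("dac_rate must be positive")
    if dac_rate == wave.sample_rate:
        return wave.with_samples(wave.samples.copy())
    frac = Fraction(dac_rate / wave.sample_rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    x = wave.samples
    # reflect-pad by one filter length to suppress edge transients
    pad = min(len(x) - 1, max(down, up) * 10)
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]]) if pad > 0 else x
    y = sps.resample_poly(xp, up, down, window=("kaiser", 5.0))
    lead = int(round(pad * up / down))
    n_out = int(round(len(x) * up / down))
    y = y[lead:lead + n_out]
    return Waveform(y, sample_rate=wave.sample_rate * up / down, units=wave.units)


def normalize_for_playback(wave: Waveform) -> tuple[Waveform, float]:
    """Scale so the most positive or negative value sits at ±1.

    Returns the normalized waveform and the physical peak value used, which
    the calibration step maps onto the converter's full scale.
    """
    if len(wave) == 0:
        raise DegenerateInputError("empty signal")
    peak = wave.peak()
    if peak == 0.0:
        raise DegenerateInputError("all-zero signal cannot be normalized")
    return wave.with_samples(wave.samples / peak, units="normalized"), peak


def build_calibration(
    signal_peak: float,
    strategy: str = "per_signal",
    dac: DacSpec | None = None,
    fixed_setting: DividerSetting | None = None,
    buffered: bool = True,
) -> CalibrationPlan:
    """Choose divider setting and digital scale for a signal's peak (volts).

    See the module docstring for the three strategies.  Raises
    :class:`UnreachableTargetError` when a fixed or hybrid configuration
    cannot span the signal's amplitude.
    """
    dac = dac or DacSpec()
    if not signal_peak > 0:
        raise DegenerateInputError("signal peak must be positive")
    peak_in = dac.fullscale / 2.0

    if strategy == "per_signal":
        setting, scale = settings_for_target_peak(signal_peak, dac.fullscale,
                                                  buffered=buffered)
    elif strategy == "fixed":
        if fixed_setting is None:
            raise ConfigurationError("fixed strategy requires fixed_setting")
        setting = fixed_setting
        cap = peak_in / attenuation_ratio(setting)
        if signal_peak > cap * (1 + 1e-12):
            raise UnreachableTargetError(
                f"signal peak {signal_peak:g} V exceeds the fixed "
                f"calibration's maximum output {cap:g} V"
            )
        scale = min(signal_peak / cap, 1.0)
    elif strategy == "hybrid":
        vpp = 2.0 * signal_peak
        coarse = (COARSE_RESISTANCES[0] if vpp > HYBRID_LARGE_SIGNAL_VPP
                  else COARSE_RESISTANCES[1])
        setting = DividerSetting(coarse, NOMINAL_POT, buffered)
        cap = peak_in / attenuation_ratio(setting)
        if signal_peak > cap * (1 + 1e-12):
            raise UnreachableTargetError(
                f"signal peak {signal_peak:g} V exceeds the hybrid "
                f"{coarse:g} ohm branch maximum {cap:g} V at the nominal pot"
            )
        scale = min(signal_peak / cap, 1.0)
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}")

    return CalibrationPlan(
        strategy=strategy,
        setting=setting,
        digital_scale=scale,
        signal_peak=signal_peak,
        reference_tone=(10.0, signal_peak),
    )


def prepare_for_playback(
    wave: Waveform,
    dac: DacSpec | None = None,
    strategy: str = "per_signal",
    dc_corner: float = 0.5,
    fixed_setting: DividerSetting | None = None,
) -> tuple[Waveform, CalibrationPlan]:
    """Full preparation pipeline: DC removal → resample → normalize → calibrate.

    The input waveform must be in volts.  Returns the normalized waveform at
    the DAC rate plus the calibration plan that maps it back to physical
    amplitude.
    """
    dac = dac or DacSpec()
    filtered = remove_dc(wave, corner=dc_corner)
    resampled = resample_to_dac(filtered, dac.sample_rate)
    normalized, peak = normalize_for_playback(resampled)
    plan = build_calibration(peak, strategy=strategy, dac=dac,
                             fixed_setting=fixed_setting)
    return normalized, plan
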