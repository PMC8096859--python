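"""Synthetic test and surrogate biosignals.

Provides every stimulus the bench protocols need with no external data:
calibration tones, full-span ramps, white and pink noise, a 130 Hz
stimulation-artifact train, and an idealized beta-band LFP burst pattern.

The LFP pattern emulates pathological beta-band activity of the kind a
closed-loop stimulator must detect: a 30 s record containing eight 1.5 s
"long bursts" of 20 Hz oscillation, separated by 2 s of silence.  Each long
burst is amplitude-modulated as five back-to-back 300 ms "short bursts"
whose amplitudes step down 50, 40, 30, 20, 10 μV, with the carrier phase
continuous across the steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .waveform import Waveform


@dataclass(frozen=True)
class LfpBurstParams:
    """Parameters of the amplitude-modulated LFP burst pattern.

    Invariants: the short bursts exactly tile a long burst
    (``n_short_bursts × short_burst_duration == long_burst_duration``), one
    amplitude per short burst, and the burst train must fit inside
    ``total_duration``.
    """

    n_long_bursts: int = 8
    long_burst_duration: float = 1.5          # s
    interburst_period: float = 2.0            # s of silence between bursts
    n_short_bursts: int = 5
    short_burst_duration: float = 0.3         # s
    short_burst_amplitudes: tuple[float, ...] = (50.0, 40.0, 30.0, 20.0, 10.0)  # μV
    carrier_frequency: float = 20.0           # Hz
    total_duration: float = 30.0              # s

    def __post_init__(self):
        if abs(self.n_short_bursts * self.short_burst_duration
               - self.long_burst_duration) > 1e-9:
            raise ConfigurationError(
                "short bursts must tile the long burst exactly: "
                f"{self.n_short_bursts} x {self.short_burst_duration} != "
                f"{self.long_burst_duration}"
            )
        if len(self.short_burst_amplitudes) != self.n_short_bursts:
            raise ConfigurationError(
                "need one amplitude per short burst "
                f"({self.n_short_bursts}), got "
                f"{len(self.short_burst_amplitudes)}"
            )
        content = (self.n_long_bursts * self.long_burst_duration
                   + self.n_long_bursts * self.interburst_period)
        if content > self.total_duration + 1e-9:
            raise ConfigurationError(
                f"burst train ({content:g} s) exceeds total_duration "
                f"({self.total_duration:g} s)"
            )


def lfp_burst_waveform(
    params: LfpBurstParams | None = None,
    sample_rate: float = 1000.0,
) -> Waveform:
    """Deterministic amplitude-modulated LFP burst pattern, in μV.

    Long bursts start at t = 0, each followed by one interburst gap; any
    remaining time up to ``total_duration`` is trailing silence.  Within a
    long burst the 20 Hz carrier runs phase-continuously under a piecewise
    constant (rectangular) envelope stepping through the configured
    amplitudes.
    """
    p = params or LfpBurstParams()
    n_total = int(round(p.total_duration * sample_rate))
    out = np.zeros(n_total)
    n_burst = int(round(p.long_burst_duration * sample_rate))
    n_short = int(round(p.short_burst_duration * sample_rate))
    period = p.long_burst_duration + p.interburst_period

    # phase-continuous carrier local to each long burst
    t_local = np.arange(n_burst) / sample_rate
    carrier = np.sin(2.0 * np.pi * p.carrier_frequency * t_local)
    envelope = np.zeros(n_burst)
    for k, amp in enumerate(p.short_burst_amplitudes):
        envelope[k * n_short:(k + 1) * n_short] = amp
    burst = envelope * carrier

    for b in range(p.n_long_bursts):
        start = int(round(b * period * sample_rate))
        out[start:start + n_burst] = burst[: max(0, min(n_burst, n_total - start))]
    return Waveform(out, sample_rate, units="uV")


def stim_artifact_train(
    stim_frequency: float = 130.0,
    on_seconds: float = 1.0,
    off_seconds: float = 8.0,
    amplitude: float = 1.0,
    sample_rate: float = 30_000.0,
    total: float = 30.0,
) -> Waveform:
    """Periodic bursts of narrow biphasic pulses emulating stimulation artifact.

    During each on-epoch, pulses occur at ``stim_frequency``; each pulse is
    one sample positive followed by one sample negative (charge balanced).
    Epochs repeat every ``on_seconds + off_seconds``, starting at t = 0.
    """
    for name, v in [("stim_frequency", stim_frequency), ("on_seconds", on_seconds),
                    ("off_seconds", off_seconds), ("sample_rate", sample_rate),
                    ("total", total)]:
        if not v > 0:
            raise ConfigurationError(f"{name} must be positive")
    n_total = int(round(total * sample_rate))
    out = np.zeros(n_total)
    epoch = on_seconds + off_seconds
    t_epoch_starts = np.arange(0.0, total, epoch)
    for t0 in t_epoch_starts:
        pulse_times = t0 + np.arange(0.0, on_seconds, 1.0 / stim_frequency)
        idx = np.round(pulse_times * sample_rate).astype(int)
        idx = idx[idx < n_total - 1]
        out[idx] += amplitude
        out[idx + 1] -= amplitude
    return Waveform(out, sample_rate, units="arb")


def tone(
    frequency: float,
    amplitude: float,
    duration: float,
    sample_rate: float,
    phase: float = 0.0,
) -> Waveform:
    """Pure sine ``A·sin(2πft + φ)``."""
    if not (frequency > 0 and duration > 0 and sample_rate > 0):
        raise ConfigurationError("frequency, duration and sample_rate must be positive")
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return Waveform(amplitude * np.sin(2 * np.pi * frequency * t + phase),
                    sample_rate, units="arb")


def ramp(
    span: tuple[float, float],
    duration: float,
    sample_rate: float,
) -> Waveform:
    """Linear ramp from ``span[0]`` to ``span[1]`` inclusive."""
    if not (duration > 0 and sample_rate > 0):
        raise ConfigurationError("duration and sample_rate must be positive")
    n = int(round(duration * sample_rate))
    if n < 2:
        raise ConfigurationError("ramp needs at least 2 samples")
    return Waveform(np.linspace(span[0], span[1], n), sample_rate, units="arb")


def gaussian_noise(
    sigma: float,
    duration: float,
    sample_rate: float,
    seed: int = 0,
) -> Waveform:
    """White Gaussian noise of standard deviation ``sigma``, seeded."""
    if not (duration > 0 and sample_rate > 0):
        raise ConfigurationError("duration and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    return Waveform(rng.normal(0.0, sigma, n), sample_rate, units="arb")


def pink_noise(
    sigma: float,
    duration: float,
    sample_rate: float,
    seed: int = 0,
) -> Waveform:
    """1/f (pink) noise, via 1/√f spectral shaping of white Gaussian noise.

    Output RMS is normalized to ``sigma``; reproducible from ``seed``.
    """
    if not (duration > 0 and sample_rate > 0):
        raise ConfigurationError("duration and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spectrum * gain, n)
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0:
        shaped *= sigma / rms
    return Waveform(shaped, sample_rate, units="arb")
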