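"""Closed-loop band-power detector with dual-threshold (hysteresis) logic.

A simplified emulation of the embedded detector in an adaptive
deep-brain-stimulation device: the re-recorded signal is band-pass filtered
to the biomarker band (beta, 16.6–26.37 Hz by default), mean-squared power
is computed over non-overlapping windows, and a hysteresis state machine
enters the stimulation state when power rises to the onset threshold
(optionally sustained for a hold time) and leaves it only when power falls
below the lower offset threshold — the two-threshold gap prevents chatter.
A stimulation-amplitude trace ramps toward each state's target current at a
fixed mA/s slew rate, emulating the device's soft transitions.

The real device uses an embedded linear-discriminant detector whose
internals are proprietary; the band-power + hysteresis machine here is a
documented simplification that reproduces the on/off behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .waveform import Waveform


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters.

    Power thresholds are in squared signal units (e.g. μV² for a μV input).
    ``offset_threshold`` must not exceed ``onset_threshold``.
    """

    band: tuple[float, float] = (16.6, 26.37)   # Hz
    window: float = 0.1                          # s, non-overlapping
    onset_threshold: float = 1.0
    offset_threshold: float = 1.0
    onset_hold: float = 0.0                      # s the onset must be sustained
    stim_amplitude_by_state: dict = field(
        default_factory=lambda: {"low": 0.0, "high": 2.0})  # mA
    ramp_rate: float = 4.0                       # mA/s
    filter_order: int = 4

    def __post_init__(self):
        if self.offset_threshold > self.onset_threshold:
            raise ConfigurationError(
                "offset_threshold must be <= onset_threshold"
            )
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigurationError("band must satisfy 0 < low < high")
        if not self.window > 0:
            raise ConfigurationError("window must be positive")
        if not self.ramp_rate > 0:
            raise ConfigurationError("ramp_rate must be positive")


@dataclass(frozen=True)
class StateInterval:
    start: float    # s
    end: float      # s
    state: str = "high"

    @property
    def duration(self) -> float:
        return self.end - self.start


def bandpower_timeseries(
    wave: Waveform,
    config: DetectorConfig | None = None,
) -> Waveform:
    """Band-limited power per non-overlapping window.

    Zero-phase Butterworth band-pass to the biomarker band, then the mean
    squared amplitude over each window; the output waveform is decimated to
    one sample per window (rate 1/window).
    """
    config = config or DetectorConfig()
    lo, hi = config.band
    nyq = wave.sample_rate / 2.0
    if hi >= nyq:
        raise ConfigurationError(
            f"band edge {hi} Hz is at or above Nyquist ({nyq} Hz)"
        )
    n_win = int(round(config.window * wave.sample_rate))
    if n_win < 2:
        raise ConfigurationError("window shorter than 2 samples")
    if config.window < 2.0 / hi:
        raise ConfigurationError(
            "window must cover at least two cycles of the band's upper edge"
        )
    sos = sps.butter(config.filter_order, [lo, hi], btype="bandpass",
                     fs=wave.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, wave.samples)
    n_windows = len(filtered) // n_win
    power = np.square(filtered[: n_windows * n_win]).reshape(
        n_windows, n_win).mean(axis=1)
    return Waveform(power, sample_rate=1.0 / config.window,
                    units=f"({wave.units})^2")


def dual_threshold_detect(
    power: Waveform,
    config: DetectorConfig | None = None,
) -> list[StateInterval]:
    """Hysteresis state machine over a band-power time series.

    Enters the high state when power has been at or above the onset
    threshold for at least ``onset_hold`` seconds; exits when power drops
    below the offset threshold.  Returns maximal high-state intervals in
    seconds (interval start is the first sample at which the onset condition
    was satisfied, i.e. hold time included).
    """
    config = config or DetectorConfig()
    p = power.samples
    dt = 1.0 / power.sample_rate
    hold_windows = int(np.ceil(config.onset_hold / dt)) if config.onset_hold > 0 else 0

    intervals: list[StateInterval] = []
    high = False
    above_run = 0
    start_time = 0.0
    for i, v in enumerate(p):
        if not high:
            if v >= config.onset_threshold:
                above_run += 1
                if above_run > hold_windows:
                    high = True
                    start_time = (i - above_run + 1) * dt
            else:
                above_run = 0
        else:
            if v < config.offset_threshold:
                intervals.append(StateInterval(start_time, i * dt))
                high = False
                above_run = 0
    if high:
        intervals.append(StateInterval(start_time, len(p) * dt))
    return intervals


def stimulation_trace(
    intervals: list[StateInterval],
    config: DetectorConfig | None = None,
    sample_rate: float = 100.0,
    total: float = 30.0,
) -> Waveform:
    """Stimulation-current trace (mA) driven by the detected state.

    The amplitude slews toward the active state's target at ``ramp_rate``
    mA/s, producing the piecewise-linear ramps and plateaus seen on a real
    device; between intervals it slews back to the low-state baseline.
    """
    config = config or DetectorConfig()
    ivs = sorted(intervals, key=lambda s: s.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ConfigurationError("state intervals must not overlap")
    for iv in ivs:
        if iv.start < 0 or iv.end > total + 1e-9:
            raise ConfigurationError(
                f"interval [{iv.start}, {iv.end}] outside [0, {total}]"
            )
    low = config.stim_amplitude_by_state.get("low", 0.0)
    n = int(round(total * sample_rate))
    dt = 1.0 / sample_rate
    step = config.ramp_rate * dt
    t = np.arange(n) * dt

    targets = np.full(n, low)
    for iv in ivs:
        target = config.stim_amplitude_by_state.get(iv.state, low)
        targets[(t >= iv.start) & (t < iv.end)] = target

    out = np.empty(n)
    level = low
    for i in range(n):
        delta = targets[i] - level
        level += np.clip(delta, -step, step)
        out[i] = level
    return Waveform(out, sample_rate, units="mA")


def detect(
    wave: Waveform,
    config: DetectorConfig | None = None,
    stim_sample_rate: float = 100.0,
) -> tuple[Waveform, list[StateInterval], Waveform]:
    """Full detector pass: band power, state intervals, stimulation trace."""
    config = config or DetectorConfig()
    power = bandpower_timeseries(wave, config)
    intervals = dual_threshold_detect(power, config)
    trace = stimulation_trace(intervals, config, sample_rate=stim_sample_rate,
                              total=wave.duration)
    return power, intervals, trace
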