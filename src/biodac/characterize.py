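"""Bench characterization protocols.

Reusable implementations of the four protocols used to validate a biosignal
playback device, applicable both to real recordings and to the output of the
simulated chain:

noise floor
    Average-periodogram (Bartlett) noise spectral density over
    non-overlapping windows, plus per-recording RMS summarized as mean ± SD.
linearity
    Repeated full-span 10 ms ramps separated by 1 s of silence; extracted
    ramps are averaged, fit with a least-squares line, and the residuals are
    normalized to the fitted slope (units of per-sample steps).
frequency response
    40 log-spaced tones from 0.1 Hz to 10 kHz, each played for 5 periods and
    preceded by a synchronization pulse; a fixed-frequency sinusoid is fit
    to each recorded tone (fits with R² < 0.95 are excluded) and the −3 dB
    corner is located by linear interpolation in log-frequency.
fidelity
    Cross-correlation alignment of a re-recorded waveform against its
    source, then Pearson correlation and RMSE on the aligned overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .dac import DacSpec
from .errors import ProtocolError
from .signals import ramp as _ramp_signal
from .waveform import Waveform

#: dB value of the half-power point, 20·log10(1/√2).
MINUS_3DB = 20.0 * np.log10(1.0 / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SineFit:
    """Result of fitting A·sin(2πft + φ) + c at a fixed frequency."""

    frequency: float
    amplitude: float
    phase: float            # radians
    offset: float
    r_squared: float

    @property
    def excluded(self) -> bool:
        """True when the fit fails the R² ≥ 0.95 quality gate."""
        return not (self.r_squared >= 0.95)


@dataclass
class LinearityResult:
    slope: float                    # output units per sample
    intercept: float
    r_squared: float
    normalized_residuals: np.ndarray  # residual / slope, per-sample steps
    mean_ramp: np.ndarray


@dataclass
class FrequencyResponse:
    frequencies: np.ndarray         # Hz, retained tones only
    magnitudes_db: np.ndarray       # relative to the passband reference
    phases_deg: np.ndarray
    phase_uncertainty_deg: np.ndarray
    r_squared: np.ndarray
    excluded_frequencies: np.ndarray


@dataclass
class FidelityResult:
    correlation: float
    rmse: float                     # original units
    lag: int                        # samples (rerecorded relative to original)


@dataclass
class CharacterizationReport:
    """Protocol label plus its results, serializable to JSON."""

    protocol: str
    results: dict

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dict__"):
                return o.__dict__
            raise TypeError(f"not serializable: {type(o)}")

        text = json.dumps({"protocol": self.protocol, "results": self.results},
                          indent=2, default=_default)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# noise floor (averaged periodogram)
# ---------------------------------------------------------------------------

def bartlett_psd(
    recordings: list[Waveform],
    window_seconds: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-periodogram amplitude spectral density, V/√Hz.

    Concatenates the recordings, splits the result into non-overlapping
    windows of ``window_seconds``, averages the unmodified (boxcar,
    untapered) one-sided periodograms, and returns the square root of the
    averaged power density.  Parseval holds: integrating the squared density
    over [0, Nyquist] recovers the time-domain mean square power.
    """
    if not recordings:
        raise ProtocolError("need at least one recording")
    fs = recordings[0].sample_rate
    if any(r.sample_rate != fs for r in recordings):
        raise ProtocolError("all recordings must share one sample rate")
    x = np.concatenate([r.samples for r in recordings])
    n_win = int(round(window_seconds * fs))
    n_windows = len(x) // n_win
    if n_windows < 1:
        raise ProtocolError(
            f"recordings too short for one {window_seconds} s window"
        )
    segments = x[: n_windows * n_win].reshape(n_windows, n_win)
    freqs, psd = sps.periodogram(segments, fs=fs, window="boxcar",
                                 detrend=False, axis=-1)
    return freqs, np.sqrt(psd.mean(axis=0))


def rms_noise(recordings: list[Waveform]) -> tuple[float, float]:
    """Per-recording RMS, summarized as (mean, standard deviation)."""
    if not recordings:
        raise ProtocolError("need at least one recording")
    values = np.array([r.rms() for r in recordings])
    return float(values.mean()), float(values.std(ddof=0))


def noise_floor_report(
    recordings: list[Waveform],
    window_seconds: float = 1.0,
) -> CharacterizationReport:
    freqs, asd = bartlett_psd(recordings, window_seconds)
    mean_rms, std_rms = rms_noise(recordings)
    return CharacterizationReport(
        protocol="noise_floor",
        results={
            "frequencies_hz": freqs,
            "density_v_per_rthz": asd,
            "rms_mean_v": mean_rms,
            "rms_std_v": std_rms,
            "n_windows": int(sum(len(r) for r in recordings)
                             // int(round(window_seconds * recordings[0].sample_rate))),
        },
    )


# ---------------------------------------------------------------------------
# linearity
# ---------------------------------------------------------------------------

def linearity_protocol(
    dac: DacSpec | None = None,
    n_ramps: int = 10,
    ramp_duration: float = 0.01,
    gap_duration: float = 1.0,
    sample_rate: float | None = None,
) -> Waveform:
    """Stimulus for the linearity protocol: repeated full-span ramps.

    Each ramp sweeps the full normalized range −1 → +1 in
    ``ramp_duration`` (10 ms, short against the AC-coupling time constant so
    droop is negligible) and is followed by ``gap_duration`` of zeros.  A
    leading gap precedes the first ramp.
    """
    dac = dac or DacSpec()
    fs = sample_rate or dac.sample_rate
    one_ramp = _ramp_signal((-1.0, 1.0), ramp_duration, fs).samples
    gap = np.zeros(int(round(gap_duration * fs)))
    parts = [gap]
    for _ in range(n_ramps):
        parts.append(one_ramp)
        parts.append(gap)
    return Waveform(np.concatenate(parts), fs, units="normalized")


def _find_ramp_segments(x: np.ndarray, n_ramps: int) -> list[tuple[int, int]]:
    """Locate ramp occurrences by activity-threshold edge detection."""
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ProtocolError("no ramps found: recording is silent")
    active = np.abs(x) > 0.2 * peak
    padded = np.concatenate([[False], active, [False]]).astype(np.int8)
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    raw = list(zip(starts.tolist(), ends.tolist()))
    if not raw:
        raise ProtocolError("no ramp regions found")
    # merge regions separated by less than half the median region length
    lengths = np.array([b - a for a, b in raw])
    gap_tol = max(1, int(np.median(lengths)))
    merged = [list(raw[0])]
    for a, b in raw[1:]:
        if a - merged[-1][1] < gap_tol:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    merged.sort(key=lambda r: r[1] - r[0], reverse=True)
    segments = sorted(merged[:n_ramps])
    if len(segments) < n_ramps:
        raise ProtocolError(
            f"expected {n_ramps} ramps, found {len(segments)}"
        )
    return [tuple(s) for s in segments]


def linearity_analysis(
    recorded: Waveform,
    n_ramps: int = 10,
) -> LinearityResult:
    """Extract and average the ramps, fit a line, normalize residuals.

    The residuals are divided by the fitted slope, expressing deviation from
    the ideal line in units of the expected increase between two adjacent
    samples.
    """
    segments = _find_ramp_segments(recorded.samples, n_ramps)
    length = min(b - a for a, b in segments)
    stack = np.stack([recorded.samples[a:a + length] for a, b in segments])
    mean_ramp = stack.mean(axis=0)
    idx = np.arange(length, dtype=np.float64)
    slope, intercept = np.polyfit(idx, mean_ramp, 1)
    fitted = slope * idx + intercept
    residuals = mean_ramp - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((mean_ramp - mean_ramp.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope == 0:
        raise ProtocolError("degenerate ramp: zero slope")
    return LinearityResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        normalized_residuals=residuals / slope,
        mean_ramp=mean_ramp,
    )


# ---------------------------------------------------------------------------
# frequency response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneScheduleEntry:
    frequency: float
    start: float      # s, tone onset in the stimulus
    end: float        # s


def freq_response_protocol(
    f_low: float = 0.1,
    f_high: float = 10_000.0,
    n_tones: int = 40,
    sample_rate: float = 192_000.0,
    amplitude: float = 1.0,
    sync_pulse_duration: float = 0.01,
    post_sync_blank: float = 2.0,
    post_tone_blank_periods: float = 2.0,
) -> tuple[Waveform, list[ToneScheduleEntry]]:
    """Stimulus and schedule for the swept-tone frequency-response protocol.

    ``n_tones`` log-spaced sines from ``f_low`` to ``f_high``; each tone
    lasts 5 of its own periods and is preceded by a full-scale rectangular
    synchronization pulse followed by a settling blank.  After each tone a
    blank of ``post_tone_blank_periods`` periods lets transients decay
    before the next sync pulse.  The schedule gives each tone's frequency
    and its onset/offset times within the stimulus.
    """
    if not (0 < f_low < f_high):
        raise ProtocolError("require 0 < f_low < f_high")
    if n_tones < 2:
        raise ProtocolError("need at least 2 tones")
    freqs = np.logspace(np.log10(f_low), np.log10(f_high), n_tones)
    fs = sample_rate
    parts: list[np.ndarray] = []
    schedule: list[ToneScheduleEntry] = []
    t_cursor = 0.0

    def _append(arr: np.ndarray):
        nonlocal t_cursor
        parts.append(arr)
        t_cursor += len(arr) / fs

    for f in freqs:
        _append(np.full(int(round(sync_pulse_duration * fs)), amplitude))
        _append(np.zeros(int(round(post_sync_blank * fs))))
        tone_dur = 5.0 / f
        n = int(round(tone_dur * fs))
        t = np.arange(n) / fs
        start = t_cursor
        _append(amplitude * np.sin(2 * np.pi * f * t))
        schedule.append(ToneScheduleEntry(frequency=float(f), start=start,
                                          end=t_cursor))
        _append(np.zeros(int(round(post_tone_blank_periods / f * fs))))
    return Waveform(np.concatenate(parts), fs, units="normalized"), schedule


def fit_sine(recorded: Waveform, frequency: float) -> SineFit:
    """Least-squares fit of A·sin(2πft + φ) + c with the frequency fixed.

    With f known the model is linear in (a, b, c) over the sin/cos basis, so
    the least-squares solution is computed exactly; amplitude and phase
    follow as A = √(a² + b²), φ = atan2(b, a).  R² is one minus the residual
    sum of squares over the total sum of squares about the mean; fits with
    R² < 0.95 are flagged excluded rather than raising.
    """
    x = recorded.samples
    if len(x) < 4:
        raise ProtocolError("need at least 4 samples to fit a sine")
    t = recorded.times()
    w = 2 * np.pi * frequency
    basis = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    a, b, c = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a))
    fitted = basis @ coef
    ss_res = float(np.sum((x - fitted) ** 2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SineFit(frequency=frequency, amplitude=amplitude, phase=phase,
                   offset=float(c), r_squared=max(0.0, min(1.0, r_squared)))


def phase_uncertainty(frequency: float, acq_rate: float) -> float:
    """Phase shift in degrees caused by a ±1-sample alignment error.

    One sample is 1/acq_rate seconds, i.e. 360·f/acq_rate degrees of the
    tone's period — growing linearly with frequency.
    """
    if not (frequency > 0 and acq_rate > 0):
        raise ProtocolError("frequency and acq_rate must be positive")
    return 360.0 * frequency / acq_rate


def minus3db_frequency(
    frequencies,
    magnitudes_db,
) -> float | None:
    """High-pass −3 dB corner by linear interpolation in log-frequency.

    Scans for an adjacent pair bracketing the −3.01 dB level with magnitude
    rising through it (the high-pass case) and interpolates log10(f)
    linearly between the two points.  Returns None when no pair brackets
    the level.
    """
    f = np.asarray(frequencies, dtype=float)
    m = np.asarray(magnitudes_db, dtype=float)
    order = np.argsort(f)
    f, m = f[order], m[order]
    for i in range(len(f) - 1):
        lo, hi = m[i], m[i + 1]
        if lo < MINUS_3DB <= hi:
            frac = (MINUS_3DB - lo) / (hi - lo)
            logf = np.log10(f[i]) + frac * (np.log10(f[i + 1]) - np.log10(f[i]))
            return float(10.0 ** logf)
    return None


def analyze_frequency_response(
    recorded: Waveform,
    schedule: list[ToneScheduleEntry],
    reference_band: tuple[float, float] = (10.0, 1000.0),
    settle_fraction: float = 0.2,
    r2_gate: float = 0.95,
) -> FrequencyResponse:
    """Fit each scheduled tone in a recording and assemble the response.

    The first ``settle_fraction`` of each tone (1 of its 5 periods by
    default) is discarded so causal-filter onset transients do not bias the
    amplitude estimate.  Magnitudes are referenced to the median fitted
    amplitude of the tones inside ``reference_band`` (the passband), so the
    plateau reads 0 dB.  Tones failing the R² gate are excluded from the
    retained arrays and reported separately.
    """
    fits: list[SineFit] = []
    for entry in schedule:
        dur = entry.end - entry.start
        seg = recorded.slice_seconds(entry.start + settle_fraction * dur,
                                     entry.end)
        if len(seg) < 4:
            fits.append(SineFit(entry.frequency, np.nan, np.nan, np.nan, 0.0))
            continue
        fits.append(fit_sine(seg, entry.frequency))

    kept = [ft for ft in fits if ft.r_squared >= r2_gate]
    excluded = np.array([ft.frequency for ft in fits if ft.r_squared < r2_gate])
    if not kept:
        raise ProtocolError("every tone failed the R-squared gate")
    ref_amps = [ft.amplitude for ft in kept
                if reference_band[0] <= ft.frequency <= reference_band[1]]
    ref = np.median(ref_amps) if ref_amps else np.median(
        [ft.amplitude for ft in kept])
    freqs = np.array([ft.frequency for ft in kept])
    mags = 20.0 * np.log10(np.array([ft.amplitude for ft in kept]) / ref)
    phases = np.degrees([ft.phase for ft in kept])
    unc = np.array([phase_uncertainty(ft.frequency, recorded.sample_rate)
                    for ft in kept])
    return FrequencyResponse(
        frequencies=freqs,
        magnitudes_db=mags,
        phases_deg=phases,
        phase_uncertainty_deg=unc,
        r_squared=np.array([ft.r_squared for ft in kept]),
        excluded_frequencies=excluded,
    )


def rolloff_slope_db_per_decade(
    response: FrequencyResponse,
    below: float,
) -> float:
    """Least-squares slope (dB/decade) of the response below a frequency.

    Used to verify the −20 dB/decade first-order stopband asymptote of a
    high-pass measured response.
    """
    mask = response.frequencies < below
    if np.count_nonzero(mask) < 2:
        raise ProtocolError("need at least two tones below the cutoff")
    logf = np.log10(response.frequencies[mask])
    slope, _ = np.polyfit(logf, response.magnitudes_db[mask], 1)
    return float(slope)


# ---------------------------------------------------------------------------
# playback fidelity
# ---------------------------------------------------------------------------

def fidelity_metrics(
    original: Waveform,
    rerecorded: Waveform,
) -> FidelityResult:
    """Align by cross-correlation, then Pearson correlation and RMSE.

    Both waveforms must share one sample rate (downsample the re-recording
    to the original's rate first).  The lag is the shift of the re-recording
    relative to the original at the cross-correlation peak; metrics are
    computed on the aligned overlap, which must cover at least half of the
    original.
    """
    if original.sample_rate != rerecorded.sample_rate:
        raise ProtocolError(
            "sample rates differ; resample the re-recording to the "
            "original's rate first"
        )
    a, b = original.samples, rerecorded.samples
    corr = sps.correlate(b - b.mean(), a - a.mean(), mode="full")
    lags = sps.correlation_lags(len(b), len(a), mode="full")
    lag = int(lags[np.argmax(corr)])
    # overlap of a[i] with b[i + lag]
    start_a = max(0, -lag)
    end_a = min(len(a), len(b) - lag)
    if end_a - start_a < 0.5 * len(a):
        raise ProtocolError(
            "aligned overlap is shorter than 50% of the original signal"
        )
    aa = a[start_a:end_a]
    bb = b[start_a + lag:end_a + lag]
    if np.std(aa) == 0 or np.std(bb) == 0:
        raise ProtocolError("constant segment: correlation undefined")
    r = float(np.corrcoef(aa, bb)[0, 1])
    rmse = float(np.sqrt(np.mean((aa - bb) ** 2)))
    return FidelityResult(correlation=r, rmse=rmse, lag=lag)
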