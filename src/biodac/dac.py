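"""Audio-DAC conversion stage: quantization, code-to-volts mapping, coupling.

Models an 8-channel, 24-bit audio converter used as a waveform source: a
symmetric mid-tread PCM quantizer, a linear code-to-voltage map with a 6.4 Vpp
full scale, and the load-dependent first-order output high-pass formed by the
AC-coupling network (datasheet corner 1 Hz into 47 kΩ; a bench-measured
0.57 Hz preset is also provided).  An optional reconstruction low-pass —
normally off, since characterization stays below 10 kHz — stands in for the
converter's sample-rate-dependent output filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DomainError
from .waveform import Waveform

logger = logging.getLogger(__name__)

#: Bench-measured high-pass corner (Hz) as an alternative to the 1 Hz
#: datasheet figure; the corner is load-dependent.
MEASURED_HIGHPASS_CORNER = 0.57


@dataclass(frozen=True)
class DacSpec:
    """Converter model parameters.

    Attributes
    ----------
    bit_depth
        PCM resolution in bits (≥ 2); default 24.
    fullscale
        Output span in volts peak-to-peak; default 6.4.
    sample_rate
        Conversion rate in Hz; the supported hardware range is
        44.1–192 kSPS.
    highpass_corner
        First-order AC-coupling corner in Hz (0 disables); default 1.0,
        the datasheet value for a 47 kΩ load.
    lowpass_corner
        Optional reconstruction low-pass corner in Hz (0 disables).
    lowpass_order
        Order of the reconstruction low-pass when enabled.
    """

    bit_depth: int = 24
    fullscale: float = 6.4
    sample_rate: float = 192_000.0
    highpass_corner: float = 1.0
    lowpass_corner: float = 0.0
    lowpass_order: int = 4

    def __post_init__(self):
        if self.bit_depth < 2:
            raise ConfigurationError("bit_depth must be at least 2")
        if not self.fullscale > 0:
            raise ConfigurationError("fullscale must be positive")
        if not (44_100 <= self.sample_rate <= 192_000):
            raise ConfigurationError(
                f"sample_rate must lie in [44100, 192000] Hz, got {self.sample_rate}"
            )
        if self.highpass_corner < 0 or self.lowpass_corner < 0:
            raise ConfigurationError("filter corners must be non-negative")

    @property
    def max_code(self) -> int:
        return 2 ** (self.bit_depth - 1) - 1

    @property
    def min_code(self) -> int:
        return -(2 ** (self.bit_depth - 1))

    @property
    def lsb(self) -> float:
        """One quantization step on the normalized [-1, 1] scale."""
        return 1.0 / self.max_code


def quantize(samples, spec: DacSpec | None = None) -> np.ndarray:
    """Quantize normalized samples in [-1, 1] to signed integer PCM codes.

    Symmetric mid-tread mapping: 0.0 maps to code 0 and ±1.0 map to
    ±(2^(b-1) − 1); rounding is to nearest with ties away from zero, the
    usual PCM convention.  Values outside [-1, 1] are clipped, with the clip
    count reported through the module logger (real converters saturate
    rather than fault).
    """
    spec = spec or DacSpec()
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        return np.zeros(0, dtype=np.int64)
    n_clipped = int(np.count_nonzero((x < -1.0) | (x > 1.0)))
    if n_clipped:
        logger.warning("quantize: %d sample(s) outside [-1, 1] clipped", n_clipped)
        x = np.clip(x, -1.0, 1.0)
    scaled = x * spec.max_code
    # round half away from zero
    codes = np.trunc(scaled + np.copysign(0.5, scaled)).astype(np.int64)
    return codes


def dequantize(codes, spec: DacSpec | None = None) -> np.ndarray:
    """Map integer codes back to the normalized [-1, 1] scale."""
    spec = spec or DacSpec()
    return np.asarray(codes, dtype=np.float64) / spec.max_code


def codes_to_volts(codes, spec: DacSpec | None = None) -> np.ndarray:
    """Linear map of PCM codes to output volts (±fullscale/2 at the rails).

    The positive rail +fullscale/2 corresponds to the maximum code
    2^(b-1) − 1.
    """
    spec = spec or DacSpec()
    c = np.asarray(codes)
    if c.size and (c.max(initial=0) > spec.max_code or c.min(initial=0) < spec.min_code):
        raise DomainError(
            f"codes outside the representable range "
            f"[{spec.min_code}, {spec.max_code}] for {spec.bit_depth} bits"
        )
    return c.astype(np.float64) * (spec.fullscale / 2.0) / spec.max_code


def dac_highpass(wave: Waveform, spec: DacSpec | None = None) -> Waveform:
    """Causal first-order high-pass modeling the DAC's AC coupling.

    Single real pole, −20 dB/decade below the corner; DC is rejected in
    steady state.  A zero corner returns the input unchanged.
    """
    spec = spec or DacSpec()
    if spec.highpass_corner == 0:
        return wave.with_samples(wave.samples.copy())
    nyquist = wave.sample_rate / 2.0
    if spec.highpass_corner >= nyquist:
        raise ConfigurationError(
            f"high-pass corner {spec.highpass_corner} Hz is at or above "
            f"Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(
        1, spec.highpass_corner, btype="highpass", fs=wave.sample_rate, output="sos"
    )
    return wave.with_samples(sps.sosfilt(sos, wave.samples))


def reconstruction_lowpass(wave: Waveform, spec: DacSpec) -> Waveform:
    """Optional output low-pass (off when ``lowpass_corner`` is 0)."""
    if spec.lowpass_corner == 0:
        return wave.with_samples(wave.samples.copy())
    nyquist = wave.sample_rate / 2.0
    if spec.lowpass_corner >= nyquist:
        raise ConfigurationError("low-pass corner at or above Nyquist")
    sos = sps.butter(
        spec.lowpass_order, spec.lowpass_corner, btype="lowpass",
        fs=wave.sample_rate, output="sos",
    )
    return wave.with_samples(sps.sosfilt(sos, wave.samples))


def vpp_to_vrms_sine(vpp: float) -> float:
    """RMS of a sine whose peak-to-peak span is ``vpp``: vpp / (2√2)."""
    if vpp < 0:
        raise DomainError("vpp must be non-negative")
    return vpp / (2.0 * np.sqrt(2.0))
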