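"""The :class:`Waveform` container used throughout the package.

A waveform is a uniformly sampled signal with an explicit sample rate and a
units label.  Samples are stored as a float64 numpy array; one-dimensional
for a single channel, ``(n_samples, n_channels)`` for multichannel data read
from or written to WAV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError


@dataclass
class Waveform:
    """A sampled signal with physical units.

    Parameters
    ----------
    samples
        Amplitude values.  Converted to a float64 array on construction.
    sample_rate
        Sampling rate in Hz; must be positive.
    units
        Free-form label for the physical units of ``samples``
        (e.g. ``"V"``, ``"uV"``, ``"normalized"``).
    """

    samples: np.ndarray
    sample_rate: float
    units: str = "V"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.sample_rate > 0:
            raise ConfigurationError(
                f"sample_rate must be positive, got {self.sample_rate}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("waveform samples must be finite")

    # -- basic geometry -----------------------------------------------------

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self) / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self)) / self.sample_rate

    # -- convenience --------------------------------------------------------

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "Waveform":
        """Copy of this waveform with new samples (and optionally new units)."""
        return replace(
            self, samples=np.asarray(samples, dtype=np.float64),
            units=self.units if units is None else units,
        )

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def peak(self) -> float:
        """Largest absolute sample value."""
        return float(np.max(np.abs(self.samples))) if len(self) else 0.0

    def slice_seconds(self, start: float, end: float) -> "Waveform":
        """Sub-waveform covering ``[start, end)`` seconds."""
        i0 = max(0, int(round(start * self.sample_rate)))
        i1 = min(len(self), int(round(end * self.sample_rate)))
        return self.with_samples(self.samples[i0:i1])
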