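"""Waveform file I/O and the playback-backend contract.

WAV support covers the formats an 8-channel audio DAC accepts: PCM 16, 24
and 32 bit plus IEEE float, little-endian RIFF, at most 8 channels.  Floats
round-trip losslessly; integer PCM round-trips within one least-significant
bit.  Delimited text files carry one column per channel with an optional
header line ``# sample_rate_hz=<r>``.

The :class:`PlaybackBackend` contract abstracts the audio driver: open a
stream, push normalized sample blocks in order, close.  :class:`MockBackend`
records every block for inspection and is the default for tests and offline
use; :class:`AudioBackend` forwards to the ``sounddevice`` package when that
is installed.
"""

from __future__ import annotations

import abc
import wave as _wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile as _wavfile

from .errors import FormatError, PlaybackError
from .waveform import Waveform

#: Device limit: channels playable simultaneously.
MAX_CHANNELS = 8

_SUPPORTED_RATES = (44_100.0, 192_000.0)  # min, max


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def _normalize_int(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1) floats."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 2**15
    if data.dtype == np.int32:
        # scipy returns 24-bit PCM as int32 shifted into the high bytes,
        # so one normalization covers both 24- and 32-bit files
        return data.astype(np.float64) / 2**31
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    raise FormatError(f"unsupported WAV sample encoding: {data.dtype}")


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF WAV file into a waveform on the normalized [-1, 1] scale.

    Integer PCM is normalized by its full-scale value; float data is passed
    through unchanged.  Files with more than 8 channels are rejected.
    """
    try:
        rate, data = _wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2 and data.shape[1] > MAX_CHANNELS:
        raise FormatError(
            f"{data.shape[1]}-channel WAV exceeds the {MAX_CHANNELS}-channel "
            f"device limit"
        )
    if np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        samples = _normalize_int(data)
    return Waveform(samples, float(rate), units="normalized")


def write_wav(
    wave_out: Waveform,
    path: str | Path,
    encoding: str = "float64",
) -> None:
    """Write a waveform as WAV.

    ``encoding`` is one of ``float32``, ``float64``, ``pcm16``, ``pcm24``,
    ``pcm32``.  PCM encodings expect samples on the normalized [-1, 1]
    scale and round to the nearest code.  ``float64`` round-trips
    bit-identically through :func:`read_wav`.
    """
    if wave_out.n_channels > MAX_CHANNELS:
        raise FormatError(
            f"{wave_out.n_channels} channels exceed the {MAX_CHANNELS}-channel "
            f"device limit"
        )
    x = wave_out.samples
    rate = int(round(wave_out.sample_rate))
    if encoding == "float64":
        _wavfile.write(str(path), rate, x)
    elif encoding == "float32":
        _wavfile.write(str(path), rate, x.astype(np.float32))
    elif encoding == "pcm16":
        _wavfile.write(str(path), rate,
                       _to_codes(x, 15).astype(np.int16))
    elif encoding == "pcm32":
        _wavfile.write(str(path), rate,
                       _to_codes(x, 31).astype(np.int32))
    elif encoding == "pcm24":
        _write_wav_pcm24(x, rate, path)
    else:
        raise FormatError(f"unsupported WAV encoding: {encoding!r}")


def _to_codes(x: np.ndarray, bits: int) -> np.ndarray:
    # standard float->PCM convention: scale by 2^bits, clip the positive rail
    scaled = np.clip(x, -1.0, 1.0) * 2**bits
    codes = np.trunc(scaled + np.copysign(0.5, scaled)).astype(np.int64)
    return np.clip(codes, -(2**bits), 2**bits - 1)


def _write_wav_pcm24(x: np.ndarray, rate: int, path: str | Path) -> None:
    """24-bit PCM writer using the stdlib wave module (3-byte samples)."""
    codes = _to_codes(x, 23)
    if codes.ndim == 1:
        frames = codes[:, None]
    else:
        frames = codes
    # pack as little-endian 3-byte two's complement via an int32 detour
    as32 = (frames.astype(np.int32) << 8).astype("<i4")
    raw = as32.tobytes()
    # drop the lowest byte of each 4-byte word (little-endian: keep 1..3)
    buf = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, 1:].tobytes()
    with _wave.open(str(path), "wb") as w:
        w.setnchannels(frames.shape[1])
        w.setsampwidth(3)
        w.setframerate(rate)
        w.writeframes(buf)


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def read_delimited(
    path: str | Path,
    sample_rate: float | None = None,
    delimiter: str | None = None,
) -> Waveform:
    """Read a delimited-text waveform (one column per channel).

    The sample rate is taken from a header line ``# sample_rate_hz=<r>``
    when present; an explicit ``sample_rate`` argument overrides it.
    """
    path = Path(path)
    rate = sample_rate
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#") and "sample_rate_hz=" in first:
        parsed = float(first.split("sample_rate_hz=")[1].strip())
        if rate is None:
            rate = parsed
    if rate is None:
        raise FormatError(
            f"{path} has no sample_rate_hz header; pass sample_rate explicitly"
        )
    data = np.loadtxt(path, delimiter=delimiter, comments="#")
    return Waveform(data, rate, units="V")


def write_delimited(
    wave_out: Waveform,
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    np.savetxt(
        path,
        wave_out.samples if wave_out.samples.ndim > 1
        else wave_out.samples[:, None],
        delimiter=delimiter,
        header=f"sample_rate_hz={wave_out.sample_rate:g}",
    )


def read_waveform(
    path: str | Path,
    sample_rate: float | None = None,
) -> Waveform:
    """Dispatch on extension: ``.wav`` → WAV, anything else → delimited."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wf = read_wav(path)
        if sample_rate is not None:
            wf = Waveform(wf.samples, sample_rate, wf.units)
        return wf
    return read_delimited(path, sample_rate=sample_rate)


def write_waveform(
    wave_out: Waveform,
    path: str | Path,
    encoding: str = "float64",
) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        write_wav(wave_out, path, encoding=encoding)
    else:
        write_delimited(wave_out, path)


# ---------------------------------------------------------------------------
# playback backends
# ---------------------------------------------------------------------------

@dataclass
class BackendCapabilities:
    max_channels: int = MAX_CHANNELS
    min_sample_rate: float = _SUPPORTED_RATES[0]
    max_sample_rate: float = _SUPPORTED_RATES[1]


class PlaybackBackend(abc.ABC):
    """Contract for streaming normalized sample blocks to a device."""

    @abc.abstractmethod
    def open(self, channels: int, sample_rate: float, buffer_size: int) -> None:
        ...

    @abc.abstractmethod
    def stream(self, block: np.ndarray) -> None:
        """Consume one block of normalized samples, in order."""

    @abc.abstractmethod
    def close(self) -> None:
        ...

    def capabilities(self) -> BackendCapabilities:
        return BackendCapabilities()


class MockBackend(PlaybackBackend):
    """Backend that records every block it is handed, for inspection."""

    def __init__(self, fail_after_blocks: int | None = None):
        self.blocks: list[np.ndarray] = []
        self.is_open = False
        self.channels = 0
        self.sample_rate = 0.0
        self.buffer_size = 0
        self._fail_after = fail_after_blocks

    def open(self, channels: int, sample_rate: float, buffer_size: int) -> None:
        caps = self.capabilities()
        if channels > caps.max_channels:
            raise FormatError(
                f"{channels} channels exceed the backend limit "
                f"{caps.max_channels}"
            )
        if not (caps.min_sample_rate <= sample_rate <= caps.max_sample_rate):
            raise FormatError(
                f"sample rate {sample_rate} outside "
                f"[{caps.min_sample_rate}, {caps.max_sample_rate}]"
            )
        self.is_open = True
        self.channels = channels
        self.sample_rate = sample_rate
        self.buffer_size = buffer_size

    def stream(self, block: np.ndarray) -> None:
        if not self.is_open:
            raise PlaybackError("stream() on a closed backend")
        if self._fail_after is not None and len(self.blocks) >= self._fail_after:
            raise PlaybackError("simulated backend failure")
        self.blocks.append(np.array(block, copy=True))

    def close(self) -> None:
        self.is_open = False

    def received(self) -> np.ndarray:
        """All streamed samples, concatenated."""
        return (np.concatenate(self.blocks) if self.blocks
                else np.zeros(0))


class AudioBackend(PlaybackBackend):
    """Real audio output through the ``sounddevice`` package, when present."""

    def __init__(self):
        try:
            import sounddevice  # noqa: F401
        except ImportError as exc:
            raise PlaybackError(
                "the 'sounddevice' package is required for real audio output; "
                "install it or use the mock backend"
            ) from exc
        self._sd = sounddevice
        self._stream = None

    def open(self, channels: int, sample_rate: float, buffer_size: int) -> None:
        self._stream = self._sd.OutputStream(
            samplerate=sample_rate, channels=channels, blocksize=buffer_size,
        )
        self._stream.start()

    def stream(self, block: np.ndarray) -> None:
        if self._stream is None:
            raise PlaybackError("stream() on a closed backend")
        self._stream.write(np.ascontiguousarray(block, dtype=np.float32))

    def close(self) -> None:
        if self._stream is not None:
            self._stream.stop()
            self._stream.close()
            self._stream = None


@dataclass
class PlaybackRecord:
    """What happened during a streaming run."""

    n_blocks: int
    samples_delivered: int
    pad_samples: int            # zeros appended to fill the final block


def stream_playback(
    wave_out: Waveform,
    backend: PlaybackBackend,
    buffer_size: int = 4096,
) -> PlaybackRecord:
    """Chunk a normalized waveform into buffers and stream it.

    The final partial block is zero-padded to the buffer size; the pad
    length is reported.  On a mock backend the concatenated received blocks
    equal the input followed by the pad, for any buffer size.  A backend
    failure mid-stream raises :class:`PlaybackError` carrying the number of
    samples already delivered.
    """
    if buffer_size < 1:
        raise FormatError("buffer_size must be at least 1")
    x = wave_out.samples
    n = len(x)
    delivered = 0
    n_blocks = 0
    pad = 0
    for start in range(0, n, buffer_size):
        block = x[start:start + buffer_size]
        if len(block) < buffer_size:
            pad = buffer_size - len(block)
            shape = (pad,) if block.ndim == 1 else (pad, block.shape[1])
            block = np.concatenate([block, np.zeros(shape)])
        try:
            backend.stream(block)
        except PlaybackError as exc:
            raise PlaybackError(
                f"backend failed after {delivered} samples: {exc}",
                samples_delivered=delivered,
            ) from exc
        delivered += min(buffer_size, n - start)
        n_blocks += 1
    return PlaybackRecord(n_blocks=n_blocks, samples_delivered=delivered,
                          pad_samples=pad)
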