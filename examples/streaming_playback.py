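"""Buffered streaming through the playback-backend contract.

Writes a prepared stimulus as 24-bit WAV (the format a real audio DAC
consumes) and streams it block-by-block through the mock backend, which
records everything it is handed.
"""

import numpy as np

import biodac as bd
from biodac.io import MockBackend, write_wav

wave = bd.tone(440.0, 0.9, 0.25, 48_000.0)
write_wav(wave, "stimulus_24bit.wav", encoding="pcm24")
print(f"Wrote stimulus_24bit.wav: {len(wave)} samples at 48 kSPS, 24-bit PCM")

backend = MockBackend()
backend.open(channels=1, sample_rate=wave.sample_rate, buffer_size=512)
record = bd.stream_playback(wave, backend, buffer_size=512)
backend.close()

received = backend.received()[: len(wave)]
print(f"Streamed {record.samples_delivered} samples in {record.n_blocks} "
      f"blocks ({record.pad_samples} zero-pad in the final block)")
print(f"Reconstruction exact: {np.array_equal(received, wave.samples)}")
print("The same stream() calls drive a real device through the audio")
print("backend when the sounddevice package is installed.")
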