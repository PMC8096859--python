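import numpy as np
import pytest

import biodac as bd

#: Sample rate used for simulated-chain protocols in tests.  Within the
#: converter's supported range and high enough to carry the 10 kHz tone of
#: the frequency-response sweep.
CHAIN_FS = 48_000.0


@pytest.fixture
def worst_case_setting():
    """Divider at the noise worst case: 1 MOhm coarse, pot at 2 kOhm."""
    return bd.DividerSetting(1e6, 2000.0)


@pytest.fixture
def dac_48k():
    return bd.DacSpec(sample_rate=CHAIN_FS)


@pytest.fixture(scope="session")
def lfp_default():
    """Default amplitude-modulated LFP burst pattern (uV, 1 kSPS)."""
    return bd.lfp_burst_waveform()


@pytest.fixture(scope="session")
def chain_frequency_response():
    """40-tone frequency-response sweep run through the simulated chain.

    DAC high-pass at the 1 Hz datasheet corner, noise off.  Session-scoped:
    the sweep stimulus is ~350 s of signal and is analyzed by several tests.
    """
    dac = bd.DacSpec(sample_rate=CHAIN_FS, highpass_corner=1.0)
    setting = bd.DividerSetting(1e6, 2000.0)
    stimulus, schedule = bd.freq_response_protocol(sample_rate=CHAIN_FS)
    recorded = bd.simulate_playback(stimulus, dac, setting, noise_on=False)
    return bd.analyze_frequency_response(recorded, schedule)
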