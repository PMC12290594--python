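import numpy as np
import pytest

from msretest import Recording, SynthConfig, simulate_recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording(rng):
    """5-channel, 250 Hz, 10 s recording with a few events."""
    data = rng.normal(size=(5, 2500)) * 20.0
    return Recording(
        data=data,
        rate=250.0,
        ch_names=["Fp1", "Fp2", "Cz", "ECG", "CWL1"],
        ch_types=["eeg", "eeg", "eeg", "ecg", "cwl"],
        events=[(10, "R"), (500, "V"), (1200, "R")],
    )


@pytest.fixture(scope="session")
def synth_recording():
    """Short microstate-structured recording with ground truth (no BCG)."""
    cfg = SynthConfig(n_channels=16, rate=250.0, duration_s=60.0,
                      noise_sd_uv=0.5, seed=3)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def synth_bcg_recording():
    """Recording with a strong planted heartbeat-locked artifact."""
    cfg = SynthConfig(n_channels=16, rate=250.0, duration_s=300.0,
                      bcg_snr=2.0, n_bcg_components=1, seed=5)
    return simulate_recording(cfg)
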