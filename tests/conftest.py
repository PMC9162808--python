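import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ewtdoppler as ed

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def phantom() -> ed.FlowPhantom:
    """Default noisy uterine-artery-like phantom (SNR 10 dB)."""
    return ed.FlowPhantom()


@pytest.fixture
def noiseless_phantom() -> ed.FlowPhantom:
    return ed.FlowPhantom(snr_db=None)


@pytest.fixture
def single_scatterer_phantom() -> ed.FlowPhantom:
    """Sample volume so small that exactly one scatterer populates a gate."""
    return ed.FlowPhantom(
        sample_volume_dims=(1e-4, 1e-4, 1e-4), snr_db=None
    )


@pytest.fixture(scope="session")
def pulsatile_indices():
    """Full envelope pipeline on a simulated pulsatile gate.

    Simulates ~6 cardiac cycles of a pulsatile centre-gate signal with a
    programmed S/D ratio of 3.0, extracts the sonogram envelope, detects
    cycles and computes the indices.  Shared between the hemodynamics unit
    tests and the acceptance suite because the simulation is the slow part.
    """
    phantom = ed.FlowPhantom(snr_db=35.0, duration=5.0, seed=11)
    wave = ed.PulsatileWaveform(heart_rate_hz=1.2, sd_ratio=3.0,
                                systolic_fraction=0.35)
    sig = ed.synthesize_gate_signal(phantom, gate_center=0.0, seed=11,
                                    pulsatile=wave)
    tf = ed.stft_spectrogram(sig, window_length=256, overlap_fraction=0.75)
    env = ed.extract_envelope(tf, phantom, percentile=95.0)
    env = ed.detect_cycles(env, min_cycles=3)
    indices = ed.compute_indices(env)
    programmed = {
        "S": sig.true_velocity,
        "D": sig.true_velocity / wave.sd_ratio,
    }
    return indices, programmed


def rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
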