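import numpy as np
import pytest

from fusikit.simulate import SimConfig
from fusikit.velocity import IQBlock


@pytest.fixture(scope="session")
def quiet_iq_sim():
    """50-block I/Q acquisition with no motion events (session-cached)."""
    from fusikit.simulate import simulate_iq

    config = SimConfig(n_blocks=50, rng_seed=11)
    blocks, gt = simulate_iq(config)
    return config, blocks, gt


@pytest.fixture(scope="session")
def quiet_pd_sim():
    """1000-frame power-Doppler-level acquisition, no events."""
    from fusikit.simulate import simulate_power_doppler

    config = SimConfig(n_blocks=1000, rng_seed=12)
    pd, gt = simulate_power_doppler(config)
    return config, pd, gt


def make_tone_block(
    f_doppler_hz: float,
    n_frames: int = 64,
    grid=(4, 4),
    f_pulse_hz: float = 15.625e6,
    f_iq_hz: float = 500.0,
) -> IQBlock:
    """Uniform complex tone: every voxel advances by the same Doppler phase."""
    t = np.arange(n_frames)
    tone = np.exp(1j * 2 * np.pi * f_doppler_hz * t / f_iq_hz)
    samples = np.broadcast_to(tone[:, None, None], (n_frames, *grid)).copy()
    return IQBlock(samples=samples, f_pulse_hz=f_pulse_hz, f_iq_hz=f_iq_hz)
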