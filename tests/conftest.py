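import numpy as np
import pytest

from usvsyntax import SonogramConfig, compute_sonogram, denoise_and_band_limit

RATE = 250_000


@pytest.fixture(scope="session")
def config():
    return SonogramConfig()


@pytest.fixture(scope="session")
def pure_tone_masked(config):
    """Denoised sonogram of a 100 ms bin-centered tone (bin 72, 70.3125 kHz)."""
    t = np.arange(int(RATE * 0.1)) / RATE
    freq = 72 * RATE / config.block_size
    wave = 0.5 * np.sin(2 * np.pi * freq * t)
    son = compute_sonogram(wave, RATE, config)
    return denoise_and_band_limit(son, config), freq / 1000.0


def make_masked_sonogram(voiced_mask, frame_step_s=0.001):
    """A one-row masked sonogram with the given boolean voicing pattern."""
    from usvsyntax import Sonogram

    voiced = np.asarray(voiced_mask, dtype=float)[None, :]
    n = voiced.shape[1]
    times = (np.arange(n) + 0.5) * frame_step_s
    return Sonogram(
        power=voiced,
        freqs_khz=np.array([70.0]),
        times_s=times,
        frame_step_s=frame_step_s,
        raw_power=voiced,
        noise_threshold=np.array([0.0]),
    )
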