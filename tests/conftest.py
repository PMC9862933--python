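import numpy as np
import pytest

import seizeflow as sf

FPS = 24.0


@pytest.fixture(scope="session")
def default_bank():
    """The default 200-frequency Gabor bank (0.5-12 Hz at 24 fps)."""
    return sf.build_bank()


@pytest.fixture(scope="session")
def small_bank():
    """A coarse bank for tests where frequency resolution is not at stake."""
    return sf.build_bank(K=60)


@pytest.fixture(scope="session")
def pattern():
    return sf.make_textured_pattern(seed=7, height=96, width=128)


def constant_rate_trial(pattern, rate_vector, n_frames, fps=FPS, noise_sd=0.0,
                        seed=0):
    """Render a short sequence under a constant rate 6-vector."""
    rates = np.tile(np.asarray(rate_vector, dtype=float), (n_frames, 1))
    program = sf.MotionProgram(duration=n_frames / fps, fps=fps, rates=rates,
                               segments=[])
    return sf.render_sequence(pattern, program, noise_sd=noise_sd, seed=seed)


def sinusoid_windows(freq, n_windows, amplitude=1.0, n_samples=35, fps=FPS,
                     channel=0, phase0=0.0):
    """Continuous sinusoidal rate stream cut into per-window (n_samples, 6)."""
    out = []
    for q in range(n_windows):
        t = (q * (n_samples + 1) + np.arange(n_samples)) / fps
        values = np.zeros((n_samples, 6))
        values[:, channel] = amplitude * np.sin(2 * np.pi * freq * t + phase0)
        out.append(values)
    return out
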