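import numpy as np
import pytest

from plectokin.trace import Trace


@pytest.fixture
def flat_noise_trace():
    """Pure Gaussian noise around a constant level: the null for step finding."""
    rng = np.random.default_rng(7)
    n = 2000
    return Trace(
        time_s=np.arange(n) / 58.0,
        extension_nm=rng.normal(0.0, 8.0, n),
        magnet_turns=np.zeros(n),
        force_pN=np.full(n, 0.5),
    )


def make_staircase(step_indices, step_sizes, n, fs=58.0, noise_sd=0.0, seed=0, level0=0.0):
    """Deterministic piecewise-constant trace with optional Gaussian noise."""
    levels = np.full(n, level0, dtype=float)
    lv = level0
    for i, s in zip(step_indices, step_sizes):
        lv += s
        levels[i:] = lv
    rng = np.random.default_rng(seed)
    y = levels + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    return Trace(np.arange(n) / fs, y, np.zeros(n), np.full(n, 0.5))


@pytest.fixture
def staircase_factory():
    return make_staircase
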