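import numpy as np
import pytest

from minicnmf import PipelineConfig, apply_shifts, estimate_motion, simulate_miniscope
from minicnmf.preprocessing import preprocess


@pytest.fixture(scope="session")
def sim_small():
    """10-cell, 64x64, 600-frame synthetic recording at signal level 1."""
    return simulate_miniscope(
        ncell=10, dims=(64, 64), nframes=600, signal_level=1.0, seed=1
    )


@pytest.fixture(scope="session")
def registered_small(sim_small):
    """sim_small after preprocessing and motion correction."""
    clean = preprocess(sim_small.video, denoise_wnd=5, background_wnd=10)
    shifts = estimate_motion(clean, chunk_nfm=3, max_shift=8)
    return apply_shifts(clean, shifts)


@pytest.fixture(scope="session")
def tiny_config():
    """Pipeline defaults used with small simulated inputs."""
    return PipelineConfig(simulate={})


def gaussian_blob(dims, center, sigma, peak=1.0):
    rows = np.arange(dims[0])[:, None]
    cols = np.arange(dims[1])[None, :]
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    fp = peak * np.exp(-r2 / (2.0 * sigma**2))
    fp[r2 > (4 * sigma) ** 2] = 0.0
    return fp.astype(np.float32)
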