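"""Synthetic miniscope-video generator with ground truth.

Emulates the structure of single-photon miniscope recordings: Gaussian-blob
cells driven by sparse spikes through an AR(2) calcium kernel, a smooth local
background field with slow temporal modulation, a static radial vignetting
profile, rigid frame-to-frame motion, and per-pixel Gaussian sensor noise,
quantized to the 8-bit scale.

Ground truth (footprints, calcium, spikes, shifts) is stored in the
unshifted frame of reference, and the whole dataset is a deterministic
function of ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter, gaussian_filter1d, shift as nd_shift
from scipy.signal import lfilter

from .core_io import video_array

#: peak fluorescence (8-bit gray levels) of a single isolated spike at a cell
#: center when ``signal_level == 1``; noise sd is 1 on the same scale, so
#: ``signal_level`` is a direct peak-SNR dial.
SPIKE_PEAK_AMPLITUDE = 25.0


@dataclass
class SimulatedDataset:
    """Synthetic video plus the ground truth it was built from."""

    video: xr.DataArray  # (frame, height, width), 8-bit scale
    truth_A: xr.DataArray  # (unit, height, width)
    truth_C: xr.DataArray  # (unit, frame)
    truth_S: xr.DataArray  # (unit, frame), binary
    truth_shifts: np.ndarray  # (frame, 2) integer (dy, dx), relative to frame 0
    truth_c_init: np.ndarray | None = None  # per-cell AR filter state at frame 0
    params: dict[str, Any] = field(default_factory=dict)


def ar2_from_time_constants(tau_rise: float, tau_decay: float, fps: float) -> tuple[float, float]:
    """Discrete AR(2) coefficients of a rise/decay double-exponential kernel."""
    r_decay = np.exp(-1.0 / (tau_decay * fps))
    r_rise = np.exp(-1.0 / (tau_rise * fps))
    return r_decay + r_rise, -r_decay * r_rise


def _place_centers(
    rng: np.random.Generator, ncell: int, dims: tuple[int, int], min_sep: float, margin: float
) -> np.ndarray:
    """Uniform cell centers with minimum separation; rejection sampling."""
    height, width = dims
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == ncell:
            break
        cand = rng.uniform([margin, margin], [height - margin, width - margin])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < ncell:
        raise ValueError(
            f"cannot place {ncell} centers with separation {min_sep} in {dims}"
        )
    return np.asarray(centers)


def _gaussian_footprints(
    centers: np.ndarray, dims: tuple[int, int], sigma: float
) -> np.ndarray:
    height, width = dims
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    A = np.zeros((len(centers), height, width), dtype=np.float32)
    for i, (cy, cx) in enumerate(centers):
        r2 = (rows - cy) ** 2 + (cols - cx) ** 2
        fp = np.exp(-r2 / (2.0 * sigma**2))
        fp[r2 > (4.0 * sigma) ** 2] = 0.0  # truncate at 4 sigma
        A[i] = fp
    return A


def _motion_walk(
    rng: np.random.Generator, nframes: int, motion_sigma: float, max_px: int = 4
) -> np.ndarray:
    """Gaussian-smoothed integer random walk, clipped to +/- max_px, start at 0."""
    if motion_sigma <= 0 or nframes == 0:
        return np.zeros((nframes, 2), dtype=int)
    steps = rng.normal(0.0, motion_sigma, size=(nframes, 2))
    walk = np.cumsum(steps, axis=0)
    walk = gaussian_filter1d(walk, sigma=10.0, axis=0)
    walk = np.clip(walk, -max_px, max_px)
    walk = np.rint(walk).astype(int)
    return walk - walk[0]


def simulate_miniscope(
    ncell: int = 30,
    dims: tuple[int, int] = (128, 128),
    nframes: int = 3000,
    signal_level: float = 1.0,
    fps: float = 30.0,
    spike_rate: float = 0.2,
    cell_sigma: float = 2.5,
    motion_sigma: float = 0.1,
    tau_rise: float = 0.1,
    tau_decay: float = 1.0,
    noise_sd: float = 1.0,
    background_amp: float = 10.0,
    vignette_amp: float = 40.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate a synthetic miniscope recording with ground truth.

    Parameters mirror the qualities of real single-photon data: ``cell_sigma``
    is the Gaussian footprint sd in pixels (cell diameter ~ 4 sigma),
    ``spike_rate`` the per-cell Bernoulli event rate in Hz, ``signal_level``
    scales the clean cell signal only (background, vignetting, and unit-sd
    noise are unaffected), and motion is a smoothed integer random walk
    clipped to +/- 4 px.
    """
    rng = np.random.default_rng(seed)
    height, width = dims

    # (1) footprints
    if ncell > 0:
        margin = 2.0 * cell_sigma
        centers = _place_centers(rng, ncell, dims, 2.0 * cell_sigma, margin)
        A = _gaussian_footprints(centers, dims, cell_sigma)
    else:
        centers = np.zeros((0, 2))
        A = np.zeros((0, height, width), dtype=np.float32)

    # (2) spikes and AR(2) calcium; a burn-in period puts the calcium process
    # in its stationary regime, so the recording does not open on an
    # unrealistically dark field (cells fire before the recording starts)
    g1, g2 = ar2_from_time_constants(tau_rise, tau_decay, fps)
    burn = int(round(10.0 * tau_decay * fps))
    S_full = (rng.random((ncell, nframes + burn)) < spike_rate / fps).astype(np.float32)
    zi0 = np.zeros((ncell, 2))
    _, zi = lfilter([1.0], [1.0, -g1, -g2], S_full[:, :burn], axis=-1, zi=zi0)
    S = S_full[:, burn:]
    C, _ = lfilter([1.0], [1.0, -g1, -g2], S, axis=-1, zi=zi)
    C = C.astype(np.float32)
    impulse = np.zeros(nframes if nframes else 1, dtype=float)
    impulse[0] = 1.0
    kernel = lfilter([1.0], [1.0, -g1, -g2], impulse)
    kernel_peak = float(kernel.max()) if nframes else 1.0

    # (3) clean cell signal, scaled so an isolated spike peaks at
    #     SPIKE_PEAK_AMPLITUDE * signal_level gray levels
    amp = SPIKE_PEAK_AMPLITUDE / kernel_peak
    clean = np.einsum("uhw,ut->thw", A, C).astype(np.float32)
    clean *= signal_level * amp

    # (4) smooth background field x slow temporal modulation, plus vignetting
    field = gaussian_filter(rng.standard_normal((height, width)), sigma=min(dims) / 4.0)
    fmin, fmax = field.min(), field.max()
    field = background_amp * (field - fmin) / max(fmax - fmin, 1e-12)
    mod = gaussian_filter1d(rng.standard_normal(nframes), sigma=100.0)
    sd = mod.std()
    mod = 1.0 + 0.2 * (mod / sd if sd > 0 else mod)
    mod = np.clip(mod, 0.0, None)
    rows = np.arange(height)[:, None] - (height - 1) / 2.0
    cols = np.arange(width)[None, :] - (width - 1) / 2.0
    rmax2 = ((height - 1) / 2.0) ** 2 + ((width - 1) / 2.0) ** 2
    vignette = vignette_amp * (1.0 - (rows**2 + cols**2) / rmax2)

    # (5) rigid motion, (6) noise and 8-bit quantization
    shifts = _motion_walk(rng, nframes, motion_sigma)
    video = np.empty((nframes, height, width), dtype=np.float32)
    base_static = (vignette + 10.0).astype(np.float32)
    for t in range(nframes):
        frame = clean[t] + field * mod[t] + base_static
        dy, dx = shifts[t]
        if dy or dx:
            frame = nd_shift(frame, (dy, dx), order=0, mode="nearest")
        video[t] = frame
    video += rng.normal(0.0, noise_sd, size=video.shape).astype(np.float32)
    np.clip(video, 0.0, 255.0, out=video)
    np.rint(video, out=video)

    unit_ids = np.arange(ncell)
    coords_hw = {"height": np.arange(height), "width": np.arange(width)}
    frames = np.arange(nframes)
    return SimulatedDataset(
        video=video_array(video, fps=fps),
        truth_A=xr.DataArray(
            A, dims=("unit", "height", "width"), coords={"unit": unit_ids, **coords_hw}
        ),
        truth_C=xr.DataArray(
            C, dims=("unit", "frame"), coords={"unit": unit_ids, "frame": frames}
        ),
        truth_S=xr.DataArray(
            S, dims=("unit", "frame"), coords={"unit": unit_ids, "frame": frames}
        ),
        truth_shifts=shifts,
        truth_c_init=zi,
        params=dict(
            ar_coefs=(float(g1), float(g2)),
            ncell=ncell,
            dims=dims,
            nframes=nframes,
            signal_level=signal_level,
            fps=fps,
            spike_rate=spike_rate,
            cell_sigma=cell_sigma,
            motion_sigma=motion_sigma,
            tau_rise=tau_rise,
            tau_decay=tau_decay,
            noise_sd=noise_sd,
            seed=seed,
        ),
    )
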