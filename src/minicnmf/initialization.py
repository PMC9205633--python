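"""Seed-based initialization of the CNMF model.

Candidate cell centers ("seeds") are local maxima of max projections over
many frame subsets; the over-complete set is then pruned by a
peak-to-noise-ratio filter, a Kolmogorov-Smirnov normality filter, and a
proximity/correlation merge, before being turned into initial spatial
footprints (windowed cosine similarity to the seed trace), temporal traces
(footprint-weighted projection of the video), and background terms.

Seeds live in a :class:`pandas.DataFrame` with columns ``row``, ``col``,
``max_intensity`` and one boolean ``mask_*`` column per refinement; a seed is
active iff every present mask is true.  Refinements only ever deactivate
seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from scipy.ndimage import maximum_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

MASK_COLUMNS = ("mask_pnr", "mask_ks", "mask_mrg")


def active_seeds(seeds: pd.DataFrame) -> pd.DataFrame:
    """Rows whose every present refinement mask is true."""
    mask = np.ones(len(seeds), dtype=bool)
    for col in MASK_COLUMNS:
        if col in seeds.columns:
            mask &= seeds[col].to_numpy()
    return seeds.loc[mask]


def seeds_init(
    video: xr.DataArray,
    wnd_size: int = 1000,
    step_size: int = 200,
    method: str = "rolling",
    n_iter: int = 10,
    max_wnd: int = 8,
    diff_thres: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Local maxima of max projections over frame subsets, unioned.

    ``max_wnd`` is the local-maximum neighborhood diameter in pixels (about
    the expected cell diameter); ``diff_thres`` the minimum projection
    intensity for a maximum to count as a seed (on the 0-255 scale a value of
    3 suffices, the video being background-subtracted).  Subsets come from a
    rolling window (``wnd_size``/``step_size``) or ``n_iter`` random draws.
    """
    data = video.values
    nfm = data.shape[0]
    if nfm == 0:
        raise ValueError("empty input: video has no frames")
    wnd_size = min(int(wnd_size), nfm)
    if method == "rolling":
        starts = range(0, max(nfm - wnd_size, 0) + 1, int(step_size))
        subsets = [slice(s, s + wnd_size) for s in starts]
    elif method == "random":
        rng = np.random.default_rng(seed)
        subsets = [
            np.sort(rng.choice(nfm, size=wnd_size, replace=False)) for _ in range(int(n_iter))
        ]
    else:
        raise ValueError(f"unknown subset method {method!r}")
    if not subsets:
        raise ValueError("no frame subsets to project")

    hits = np.zeros(data.shape[1:], dtype=bool)
    for sub in subsets:
        proj = data[sub].max(axis=0)
        local_max = maximum_filter(proj, size=int(max_wnd), mode="reflect")
        hits |= (proj == local_max) & (proj > diff_thres)
    global_max = data.max(axis=0)
    rows, cols = np.nonzero(hits)
    seeds = pd.DataFrame(
        {"row": rows, "col": cols, "max_intensity": global_max[rows, cols]}
    )
    return seeds.reset_index(drop=True)


def filter_trace(
    trace: np.ndarray, cutoff: float, btype: str, fps: float = 30.0
) -> np.ndarray:
    """Brick-wall frequency-domain filter along the last axis.

    The low- and high-pass components partition the signal exactly
    (``low + high == trace``); the low-pass component retains DC.
    """
    if not 0 < cutoff < fps / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {fps / 2}) Hz")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    spec = np.fft.rfft(trace, axis=-1)
    low_spec = np.where(freqs <= cutoff, spec, 0.0)
    if btype == "low":
        return np.fft.irfft(low_spec, n=n, axis=-1)
    if btype == "high":
        return np.fft.irfft(spec - low_spec, n=n, axis=-1)
    raise ValueError(f"btype must be 'low' or 'high', got {btype!r}")


def seed_traces(video: xr.DataArray, seeds: pd.DataFrame) -> np.ndarray:
    """(n_seed, T) fluorescence traces at the seed pixels."""
    data = video.values
    return data[:, seeds["row"].to_numpy(), seeds["col"].to_numpy()].T.copy()


def pnr_refine(
    video: xr.DataArray,
    seeds: pd.DataFrame,
    noise_freq: float = 1.0,
    thres: float = 1.0,
) -> pd.DataFrame:
    """Keep seeds whose signal-band peak-to-peak exceeds ``thres`` x the noise band's.

    pnr = ptp(low-pass) / ptp(high-pass); a zero noise band gives pnr = +inf
    and the seed is kept.
    """
    seeds = seeds.copy()
    act = active_seeds(seeds)
    fps = float(video.attrs.get("fps", 30.0))
    traces = seed_traces(video, act)
    low = filter_trace(traces, noise_freq, "low", fps)
    high = filter_trace(traces, noise_freq, "high", fps)
    noise_ptp = np.ptp(high, axis=-1)
    with np.errstate(divide="ignore"):
        pnr = np.where(noise_ptp > 0, np.ptp(low, axis=-1) / noise_ptp, np.inf)
    seeds["mask_pnr"] = False
    seeds.loc[act.index, "mask_pnr"] = pnr > thres
    return seeds


def ks_refine(
    video: xr.DataArray, seeds: pd.DataFrame, sig: float = 0.05
) -> pd.DataFrame:
    """Keep seeds whose z-scored trace is non-normal by a one-sample KS test.

    A calcium-carrying trace mixes a Gaussian noise floor with sparse large
    transients, so normality is rejected; pure-noise seeds are discarded.
    Constant traces are removed.
    """
    seeds = seeds.copy()
    act = active_seeds(seeds)
    traces = seed_traces(video, act)
    keep = np.zeros(len(act), dtype=bool)
    for i, tr in enumerate(traces):
        sd = tr.std()
        if sd == 0:
            continue
        z = (tr - tr.mean()) / sd
        keep[i] = stats.kstest(z, "norm").pvalue < sig
    seeds["mask_ks"] = False
    seeds.loc[act.index, "mask_ks"] = keep
    return seeds


def seeds_merge(
    video: xr.DataArray,
    seeds: pd.DataFrame,
    thres_dist: float = 8.0,
    thres_corr: float = 0.8,
    noise_freq: float = 1.0,
) -> pd.DataFrame:
    """Collapse groups of nearby, correlated seeds to their brightest member.

    Seeds within ``thres_dist`` px whose low-pass-smoothed traces correlate
    at >= ``thres_corr`` are linked; per connected component only the seed
    with the highest ``max_intensity`` stays active.
    """
    seeds = seeds.copy()
    act = active_seeds(seeds)
    n = len(act)
    seeds["mask_mrg"] = False
    if n == 0:
        return seeds
    fps = float(video.attrs.get("fps", 30.0))
    coords = act[["row", "col"]].to_numpy(dtype=float)
    smoothed = filter_trace(seed_traces(video, act), noise_freq, "low", fps)
    smoothed = smoothed - smoothed.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(smoothed, axis=-1)
    pairs = cKDTree(coords).query_pairs(thres_dist, output_type="ndarray")
    links = []
    for i, j in pairs:
        denom = norms[i] * norms[j]
        corr = smoothed[i] @ smoothed[j] / denom if denom > 0 else 0.0
        if corr >= thres_corr:
            links.append((i, j))
    if links:
        ij = np.asarray(links)
        graph = csr_matrix(
            (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    keep = np.zeros(n, dtype=bool)
    intensity = act["max_intensity"].to_numpy()
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        keep[members[np.argmax(intensity[members])]] = True
    seeds.loc[act.index, "mask_mrg"] = keep
    return seeds


def init_spatial(
    video: xr.DataArray,
    seeds: pd.DataFrame,
    thres_corr: float = 0.5,
    wnd: int = 8,
) -> xr.DataArray:
    """Initial footprints from windowed cosine similarity to each seed trace.

    Weights below ``thres_corr`` are zeroed, the window is a square of radius
    ``wnd`` pixels around the seed, and the seed pixel itself has weight 1.
    """
    act = active_seeds(seeds)
    if len(act) == 0:
        raise ValueError("no active seeds")
    data = video.values
    nfm, height, width = data.shape
    A = np.zeros((len(act), height, width), dtype=np.float32)
    for i, (_, sd) in enumerate(act.iterrows()):
        r, c = int(sd["row"]), int(sd["col"])
        r0, r1 = max(0, r - wnd), min(height, r + wnd + 1)
        c0, c1 = max(0, c - wnd), min(width, c + wnd + 1)
        block = data[:, r0:r1, c0:c1].reshape(nfm, -1)
        ref = data[:, r, c]
        ref_norm = np.linalg.norm(ref)
        norms = np.linalg.norm(block, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(
                (norms > 0) & (ref_norm > 0), ref @ block / (norms * ref_norm), 0.0
            )
        sim[sim < thres_corr] = 0.0
        A[i, r0:r1, c0:c1] = sim.reshape(r1 - r0, c1 - c0)
        A[i, r, c] = 1.0
    return xr.DataArray(
        A,
        dims=("unit", "height", "width"),
        coords={
            "unit": np.arange(len(act)),
            "height": np.arange(height),
            "width": np.arange(width),
        },
        name="A",
    )


def init_temporal(video: xr.DataArray, A: xr.DataArray) -> xr.DataArray:
    """C[i, t] = <A_i, Y_t> / ||A_i||^2 — footprint-weighted video projection."""
    Af = A.values.reshape(A.sizes["unit"], -1)
    norms = (Af**2).sum(axis=1)
    if np.any(norms == 0):
        raise ValueError("zero footprint in A")
    Yf = video.values.reshape(video.sizes["frame"], -1)
    C = (Af @ Yf.T) / norms[:, None]
    return xr.DataArray(
        C.astype(np.float32),
        dims=("unit", "frame"),
        coords={"unit": A.coords["unit"].values, "frame": video.coords["frame"].values},
        name="C",
    )


def init_background(
    video: xr.DataArray, A: xr.DataArray, C: xr.DataArray
) -> tuple[xr.DataArray, xr.DataArray]:
    """Mean spatial / temporal projections of the non-negative residual Y - AC."""
    Af = A.values.reshape(A.sizes["unit"], -1)
    Cv = C.values
    Yf = video.values.reshape(video.sizes["frame"], -1)
    b = np.zeros(Yf.shape[1], dtype=np.float64)
    f = np.zeros(Yf.shape[0], dtype=np.float64)
    block = 512
    for s in range(0, Yf.shape[0], block):
        sl = slice(s, min(s + block, Yf.shape[0]))
        resid = Yf[sl] - Cv[:, sl].T @ Af
        np.clip(resid, 0.0, None, out=resid)
        b += resid.sum(axis=0)
        f[sl] = resid.mean(axis=1)
    b /= Yf.shape[0]
    height, width = video.shape[1:]
    b_da = xr.DataArray(
        b.reshape(height, width).astype(np.float32),
        dims=("height", "width"),
        coords={"height": np.arange(height), "width": np.arange(width)},
        name="b",
    )
    f_da = xr.DataArray(
        f.astype(np.float32),
        dims=("frame",),
        coords={"frame": video.coords["frame"].values},
        name="f",
    )
    return b_da, f_da
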