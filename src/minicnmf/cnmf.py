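"""Constrained non-negative matrix factorization of the preprocessed video.

The model is Y = AC + bf + E: non-negative footprints A (unit, height,
width), calcium traces C (unit, frame), a rank-one background bf, and
residual noise E (always derived as Y - AC - bf, never stored).  Fitting
alternates two convex subproblems:

* spatial update — for every pixel p an independent non-negative lasso over
  the units whose (dilated) footprints cover p, with the background treated
  as one extra component and a per-pixel penalty ``sparse_penalty * sn(p) *
  sqrt(T)`` set by the estimated noise level;
* temporal update — per unit, the video is projected onto the footprint
  (subtracting the contribution of overlapping neighbours), an AR(p) model
  of the calcium impulse response is estimated by Yule-Walker, and the trace
  is deconvolved by minimizing ``||y - c - b0 - c0*d||^2 + lambda*||Gc||_1``
  subject to ``c, Gc >= 0``, where ``s = Gc`` is the spike signal, ``b0`` a
  constant baseline, and ``c0*d`` the decay of calcium present before the
  recording started.

The spatial solver is cyclic coordinate descent on each pixel's lasso (all
pixels sharing a unit pattern are swept together); the temporal solver is
projected accelerated gradient (FISTA) on the spike-domain reformulation
``c = conv(d, s)``, which turns both constraints into simple
non-negativity.  Both are checked against generic constrained-QP oracles in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import binary_dilation
from scipy.signal import lfilter
from scipy.sparse import csr_matrix, diags
from scipy.sparse.csgraph import connected_components
from skimage.morphology import disk

from .initialization import filter_trace


# --------------------------------------------------------------------------
# model containers
# --------------------------------------------------------------------------


@dataclass
class CNMFModel:
    """A, C, S share the unit axis; E = Y - AC - bf is derived on demand."""

    A: xr.DataArray  # (unit, height, width)
    C: xr.DataArray  # (unit, frame)
    b: xr.DataArray  # (height, width)
    f: xr.DataArray  # (frame,)
    S: xr.DataArray | None = None  # (unit, frame)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.A.coords["unit"].values

    def residual(self, video: xr.DataArray) -> xr.DataArray:
        Af = self.A.values.reshape(self.A.sizes["unit"], -1)
        recon = self.C.values.T @ Af + np.outer(self.f.values, self.b.values.ravel())
        res = video.values.reshape(video.sizes["frame"], -1) - recon
        return video.copy(data=res.reshape(video.shape))


@dataclass(frozen=True)
class ARParams:
    """Stable AR(p) calcium model: coefficients, derived kernel, noise level."""

    order: int
    coefs: tuple[float, ...]
    noise_sd: float

    @property
    def poly(self) -> np.ndarray:
        """Denominator polynomial [1, -g1, ..., -gp]; G is banded with these rows."""
        return np.concatenate(([1.0], -np.asarray(self.coefs)))

    def impulse_response(self, nframes: int) -> np.ndarray:
        """d: response of the AR filter to a unit impulse; d[0] = 1, d >= 0."""
        impulse = np.zeros(nframes)
        impulse[0] = 1.0
        return lfilter([1.0], self.poly, impulse)

    def G(self, nframes: int):
        """Sparse (T, T) banded matrix with 1 on the diagonal and -gk below."""
        offsets = [0] + [-(k + 1) for k in range(self.order)]
        data = [np.ones(nframes)] + [
            np.full(nframes, -g) for g in self.coefs
        ]
        return diags(
            [d[: nframes - abs(o)] for d, o in zip(data, offsets)], offsets
        ).tocsr()


@dataclass
class TemporalFit:
    """Per-unit temporal solution; fitted signal = c + b0 + c0 * d."""

    c: np.ndarray
    s: np.ndarray
    b0: float
    c0: float
    scale: float
    y_ra: np.ndarray
    ar: ARParams
    converged: bool = True


# --------------------------------------------------------------------------
# noise estimation
# --------------------------------------------------------------------------


def _high_band_fraction(nframes: int, cutoff: float, fps: float) -> float:
    freqs = np.fft.rfftfreq(nframes, d=1.0 / fps)
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if nframes % 2 == 0:
        weights[-1] = 1.0
    return float(weights[freqs > cutoff].sum() / nframes)


def noise_std(traces: np.ndarray, cutoff: float, fps: float) -> np.ndarray:
    """Per-trace noise sd from the high band, unbiased for white noise.

    The high-pass component carries only the fraction of total power lying
    above ``cutoff``; dividing the band's mean square by that fraction makes
    i.i.d. noise of sd sigma yield sn -> sigma.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    frac = _high_band_fraction(traces.shape[-1], cutoff, fps)
    if frac == 0:
        return np.zeros(traces.shape[0])
    high = filter_trace(traces, cutoff, "high", fps)
    return np.sqrt((high**2).mean(axis=-1) / frac)


def estimate_noise(video: xr.DataArray, noise_freq: float = 1.0) -> xr.DataArray:
    """Per-pixel noise sd map from the power above ``noise_freq``."""
    fps = float(video.attrs.get("fps", 30.0))
    nfm, height, width = video.shape
    flat = video.values.reshape(nfm, -1).T
    sn = np.empty(flat.shape[0])
    block = 4096
    for s in range(0, flat.shape[0], block):
        sl = slice(s, min(s + block, flat.shape[0]))
        sn[sl] = noise_std(flat[sl], noise_freq, fps)
    return xr.DataArray(
        sn.reshape(height, width).astype(np.float32),
        dims=("height", "width"),
        coords={"height": np.arange(height), "width": np.arange(width)},
        name="sn",
    )


# --------------------------------------------------------------------------
# spatial update
# --------------------------------------------------------------------------


def update_spatial(
    Y: xr.DataArray,
    A: xr.DataArray,
    C: xr.DataArray,
    b: xr.DataArray,
    f: xr.DataArray,
    sn: xr.DataArray,
    dl_wnd: int = 8,
    sparse_penalty: float = 0.1,
    max_sweeps: int = 500,
    tol: float = 1e-5,
) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray]:
    """Per-pixel non-negative lasso refit of footprints and background.

    Each pixel solves ``min ||Y(p,:) - a^T M||^2 + lambda_p ||a||_1, a >= 0``
    over the traces M of the units whose support (dilated by a disk of
    diameter ``dl_wnd``) covers p, plus the background trace f; ``lambda_p =
    sparse_penalty * sn(p) * sqrt(T)``.  Afterwards the background trace is
    recomputed as the projection of Y - AC onto the new b, and units with
    empty footprints are dropped.
    """
    nunit = A.sizes["unit"]
    nfm = Y.sizes["frame"]
    height, width = Y.shape[1:]
    npix = height * width
    Yf = Y.values.reshape(nfm, -1)
    Af = A.values.reshape(nunit, npix)
    Cv = np.asarray(C.values, dtype=np.float64).reshape(nunit, nfm)
    fv = np.asarray(f.values, dtype=np.float64)

    # candidate units per pixel: dilated footprint support
    selem = disk(max(1, int(dl_wnd) // 2))
    supports = np.zeros((nunit, npix), dtype=bool)
    for i in range(nunit):
        supports[i] = binary_dilation(
            Af[i].reshape(height, width) > 0, structure=selem
        ).ravel()

    comps = np.vstack([Cv, fv[None, :]])  # background is one extra component
    gram = comps @ comps.T
    rhs = comps @ Yf  # (nunit+1, npix)
    lam = sparse_penalty * sn.values.ravel().astype(np.float64) * np.sqrt(nfm)

    coef = np.vstack([Af.astype(np.float64), b.values.ravel()[None, :]])
    if nunit > 0:
        packed = np.packbits(supports, axis=0)
        _, inverse = np.unique(packed, axis=1, return_inverse=True)
    else:  # background-only model: one group covering every pixel
        inverse = np.zeros(npix, dtype=int)
    for gid in np.unique(inverse):
        pix = np.nonzero(inverse == gid)[0]
        units = np.nonzero(supports[:, pix[0]])[0]
        active = np.concatenate([units, [nunit]])  # background always active
        sub_g = gram[np.ix_(active, active)]
        diag = np.diag(sub_g).copy()
        a = coef[np.ix_(active, pix)]
        a[diag == 0] = 0.0
        rhs_g = rhs[np.ix_(active, pix)]
        lam_g = lam[pix]
        inactive = np.setdiff1d(np.arange(nunit), units)
        coef[np.ix_(inactive, pix)] = 0.0
        for _ in range(max_sweeps):
            delta = 0.0
            for u in range(len(active)):
                if diag[u] == 0:
                    continue
                partial = rhs_g[u] - sub_g[u] @ a + diag[u] * a[u]
                new = np.maximum(0.0, (partial - lam_g / 2.0) / diag[u])
                delta = max(delta, float(np.abs(new - a[u]).max(initial=0.0)))
                a[u] = new
            if delta < tol:
                break
        coef[np.ix_(active, pix)] = a

    new_Af = coef[:nunit]
    new_b = coef[nunit]
    keep = np.nonzero(new_Af.any(axis=1))[0]
    new_Af = new_Af[keep]
    Ck = Cv[keep]

    # background trace: projection of the cell-free residual onto new b
    bb = float(new_b @ new_b)
    if bb > 0:
        Ab = new_Af @ new_b
        new_f = (Yf @ new_b - Ck.T @ Ab) / bb
        np.clip(new_f, 0.0, None, out=new_f)
    else:
        new_f = np.zeros(nfm)

    unit_coord = A.coords["unit"].values[keep]
    A_out = xr.DataArray(
        new_Af.reshape(len(keep), height, width).astype(np.float32),
        dims=("unit", "height", "width"),
        coords={
            "unit": unit_coord,
            "height": A.coords["height"].values,
            "width": A.coords["width"].values,
        },
        name="A",
    )
    b_out = b.copy(data=new_b.reshape(height, width).astype(np.float32))
    f_out = f.copy(data=new_f.astype(np.float32))
    return A_out, b_out, f_out


def spatial_objective(
    y: np.ndarray, comps: np.ndarray, a: np.ndarray, lam: float
) -> float:
    """||y - a^T comps||^2 + lam * ||a||_1 for one pixel (diagnostic/oracle)."""
    resid = y - a @ comps
    return float(resid @ resid + lam * np.abs(a).sum())


# --------------------------------------------------------------------------
# AR coefficient estimation
# --------------------------------------------------------------------------


def estimate_ar_coefs(
    trace: np.ndarray,
    noise_freq: float = 1.0,
    p: int = 2,
    fps: float = 30.0,
    lags: int = 20,
) -> ARParams:
    """AR(p) fit of a calcium trace from its autocovariance (Yule-Walker).

    The Yule-Walker recursion ``r_k = sum_j g_j r_{k-j}`` is solved in least
    squares over lags ``p+1 .. lags``.  Starting above lag p keeps the
    white-noise floor (which only contaminates lag 0) out of the system, so
    the time constants are not biased by high-frequency noise; the extra
    lags stabilize the fit when the driving spikes are sparse.  Estimates
    with spectral radius >= 1 are shrunk to 0.99; an AR(2) estimate whose
    roots are complex or negative (oscillating impulse response, so d would
    go negative) falls back to AR(1).  ``noise_freq`` sets the band for the
    per-unit noise sd.
    """
    if p not in (1, 2):
        raise ValueError("AR order must be 1 or 2")
    trace = np.asarray(trace, dtype=float)
    noise_sd = float(noise_std(trace[None, :], noise_freq, fps)[0])
    x = trace - trace.mean()
    n = len(x)
    nlag = max(int(lags), p + 1)
    if n <= nlag + 1:
        raise ValueError("trace too short for AR estimation")
    r = np.array([x[: n - k] @ x[k:] / n for k in range(nlag + 1)])
    if r[0] <= 0:
        return ARParams(order=1, coefs=(0.0,), noise_sd=noise_sd)

    def _fit(order: int) -> np.ndarray | None:
        ks = np.arange(order + 1, nlag + 1)
        X = np.stack([r[ks - j] for j in range(1, order + 1)], axis=1)
        if not np.any(np.abs(X) > 0):
            return None
        g, *_ = np.linalg.lstsq(X, r[ks], rcond=None)
        return g

    def _ar1() -> ARParams:
        g = _fit(1)
        val = float(np.clip(g[0], 0.0, 0.99)) if g is not None else 0.0
        return ARParams(order=1, coefs=(val,), noise_sd=noise_sd)

    if p == 1:
        return _ar1()
    g = _fit(2)
    if g is None:
        return _ar1()
    roots = np.roots([1.0, -g[0], -g[1]])
    if np.any(np.abs(roots.imag) > 1e-10) or np.any(roots.real < 0):
        return _ar1()
    roots = roots.real
    radius = roots.max()
    if radius >= 1.0:
        roots = roots * (0.99 / radius)
    return ARParams(
        order=2,
        coefs=(float(roots.sum()), float(-roots.prod())),
        noise_sd=noise_sd,
    )


# --------------------------------------------------------------------------
# temporal update
# --------------------------------------------------------------------------


def project_traces(
    Y: xr.DataArray,
    A: xr.DataArray,
    b: xr.DataArray,
    f: xr.DataArray,
    C: xr.DataArray,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-unit traces: video projected on footprints, neighbours removed.

    y_ra(i) = [A_i . (Y - bf) - sum_{j!=i} (A_i . A_j) C(j,:)] / (A_i . A_i).
    Returns (y_ra, kept unit positions); zero-norm footprints are dropped
    with a warning.
    """
    nunit = A.sizes["unit"]
    Af = A.values.reshape(nunit, -1).astype(np.float64)
    norms = (Af**2).sum(axis=1)
    keep = np.nonzero(norms > 0)[0]
    if len(keep) < nunit:
        warnings.warn(f"dropping {nunit - len(keep)} unit(s) with empty footprints")
    Af = Af[keep]
    norms = norms[keep]
    Yf = Y.values.reshape(Y.sizes["frame"], -1)
    AY = Af @ Yf.T  # (k, T)
    Ab = Af @ b.values.ravel()
    AY -= np.outer(Ab, f.values)
    AA = Af @ Af.T
    cross = AA - np.diag(np.diag(AA))
    y_ra = (AY - cross @ C.values[keep]) / norms[:, None]
    return y_ra, keep


def _power_lipschitz(poly: np.ndarray, d: np.ndarray, nframes: int) -> float:
    """Largest eigenvalue of M^T M for M = [conv(d, .), 1, d], by power iteration."""

    def M(x):
        return lfilter([1.0], poly, x[:-2]) + x[-2] + x[-1] * d

    def MT(r):
        back = lfilter([1.0], poly, r[::-1])[::-1]
        return np.concatenate([back, [r.sum()], [d @ r]])

    v = np.ones(nframes + 2)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(50):
        w = MT(M(v))
        lam = np.linalg.norm(w)
        if lam == 0:
            return 1.0
        v = w / lam
    return float(lam)


def temporal_objective(
    y: np.ndarray, fit: TemporalFit, lam: float | None = None
) -> float:
    """||y - c - b0 - c0 d||^2 + lam * sum(Gc) at a temporal solution."""
    d = fit.ar.impulse_response(len(y))
    resid = y - fit.c - fit.b0 - fit.c0 * d
    if lam is None:
        lam = 0.0
    return float(resid @ resid + lam * fit.s.sum())


def solve_temporal_unit(
    y_ra: np.ndarray,
    ar: ARParams,
    sparse_penalty: float = 0.008,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> TemporalFit:
    """Deconvolve one unit's projected trace under the AR model.

    Solves ``min ||y - c - b0 - c0 d||^2 + lambda 1^T (Gc)`` s.t.
    ``c, Gc, b0, c0 >= 0`` with ``lambda = sparse_penalty * noise_sd *
    sqrt(T)``, in the spike domain ``c = conv(d, s)`` by projected FISTA,
    then rescales all fitted signals by the non-negative least-squares factor
    matching the raw trace (the l1 term shrinks amplitudes; the post-hoc
    scale restores them).
    """
    y = np.asarray(y_ra, dtype=np.float64)
    nframes = len(y)
    poly = ar.poly
    d = ar.impulse_response(nframes)
    lam = sparse_penalty * ar.noise_sd * np.sqrt(nframes)

    def model(x: np.ndarray) -> np.ndarray:
        return lfilter([1.0], poly, x[:-2]) + x[-2] + x[-1] * d

    def adjoint(r: np.ndarray) -> np.ndarray:
        back = lfilter([1.0], poly, r[::-1])[::-1]
        return np.concatenate([back, [r.sum()], [d @ r]])

    lip = 2.0 * _power_lipschitz(poly, d, nframes) * 1.01
    lam_vec = np.concatenate([np.full(nframes, lam), [0.0, 0.0]])

    def objective(x: np.ndarray) -> float:
        resid = model(x) - y
        return float(resid @ resid + lam_vec @ x)

    x = np.zeros(nframes + 2)
    z = x.copy()
    t_acc = 1.0
    f_prev = objective(x)
    converged = False
    for _ in range(max_iter):
        grad = 2.0 * adjoint(model(z) - y) + lam_vec
        x_new = np.maximum(0.0, z - grad / lip)
        f_new = objective(x_new)
        if f_new > f_prev:  # restart acceleration when monotonicity breaks
            z = x.copy()
            t_acc = 1.0
            grad = 2.0 * adjoint(model(z) - y) + lam_vec
            x_new = np.maximum(0.0, z - grad / lip)
            f_new = objective(x_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        z = x_new + ((t_acc - 1.0) / t_new) * (x_new - x)
        x, t_acc = x_new, t_new
        if abs(f_prev - f_new) <= tol * max(1.0, abs(f_new)):
            converged = True
            break
        f_prev = f_new

    s = x[:-2]
    b0, c0 = float(x[-2]), float(x[-1])
    c = lfilter([1.0], poly, s)
    fitted = c + b0 + c0 * d
    denom = float(fitted @ fitted)
    scale = max(0.0, float(y @ fitted) / denom) if denom > 0 else 0.0
    return TemporalFit(
        c=c * scale,
        s=s * scale,
        b0=b0 * scale,
        c0=c0 * scale,
        scale=scale,
        y_ra=y,
        ar=ar,
        converged=converged,
    )


def overlap_groups(A: xr.DataArray, jac_thres: float = 0.2) -> list[np.ndarray]:
    """Connected components of the footprint-support graph with Jaccard > thres.

    Units in different groups do not meaningfully overlap and may be solved
    concurrently; the solution is order-invariant either way because every
    unit's problem depends only on the fixed projected trace.
    """
    nunit = A.sizes["unit"]
    sup = csr_matrix(A.values.reshape(nunit, -1) > 0)
    inter = (sup @ sup.T).toarray().astype(float)
    sizes = np.asarray(sup.sum(axis=1)).ravel().astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    adj = csr_matrix(np.triu(jac > jac_thres, k=1))
    _, labels = connected_components(adj, directed=False)
    return [np.nonzero(labels == lab)[0] for lab in np.unique(labels)]


def update_temporal(
    Y: xr.DataArray,
    A: xr.DataArray,
    C: xr.DataArray,
    b: xr.DataArray,
    f: xr.DataArray,
    p: int = 2,
    noise_freq: float = 1.0,
    sparse_penalty: float = 0.008,
    jac_thres: float = 0.2,
) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray, dict[int, TemporalFit]]:
    """Deconvolve every unit; returns (A', C', S', per-unit fits).

    Units whose fitted calcium is identically zero are dropped (A' carries
    the surviving unit axis so downstream stages stay consistent).
    """
    fps = float(Y.attrs.get("fps", 30.0))
    y_ra, keep = project_traces(Y, A, b, f, C)
    A = A.isel(unit=keep)
    unit_coord = A.coords["unit"].values
    groups = overlap_groups(A, jac_thres)
    order = np.concatenate(groups) if groups else np.array([], dtype=int)

    nframes = Y.sizes["frame"]
    fits: dict[int, TemporalFit] = {}
    new_C = np.zeros((len(unit_coord), nframes), dtype=np.float64)
    new_S = np.zeros_like(new_C)
    for i in sorted(order.tolist()):
        ar = estimate_ar_coefs(y_ra[i], noise_freq=noise_freq, p=p, fps=fps)
        fit = solve_temporal_unit(y_ra[i], ar, sparse_penalty=sparse_penalty)
        fits[int(unit_coord[i])] = fit
        new_C[i] = fit.c
        new_S[i] = fit.s

    alive = np.nonzero(new_C.any(axis=1))[0]
    fits = {int(unit_coord[i]): fits[int(unit_coord[i])] for i in alive}
    frame_coord = Y.coords["frame"].values
    C_out = xr.DataArray(
        new_C[alive].astype(np.float32),
        dims=("unit", "frame"),
        coords={"unit": unit_coord[alive], "frame": frame_coord},
        name="C",
    )
    S_out = C_out.copy(data=new_S[alive].astype(np.float32)).rename("S")
    return A.isel(unit=alive), C_out, S_out, fits


# --------------------------------------------------------------------------
# merging and curation
# --------------------------------------------------------------------------


def _merge_components(
    A: xr.DataArray, C: xr.DataArray, labels: np.ndarray
) -> tuple[xr.DataArray, xr.DataArray]:
    """Merge units sharing a label: footprint sum, trace mean, smallest id."""
    unit_ids = A.coords["unit"].values
    Av, Cv = A.values, C.values
    out_ids, out_A, out_C = [], [], []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        out_ids.append(unit_ids[members].min())
        out_A.append(Av[members].sum(axis=0))
        out_C.append(Cv[members].mean(axis=0))
    order = np.argsort(out_ids)
    A_out = xr.DataArray(
        np.stack([out_A[i] for i in order]),
        dims=A.dims,
        coords={**{d: A.coords[d].values for d in A.dims[1:]}, "unit": np.asarray(out_ids)[order]},
        name="A",
    )
    C_out = xr.DataArray(
        np.stack([out_C[i] for i in order]),
        dims=C.dims,
        coords={**{d: C.coords[d].values for d in C.dims[1:]}, "unit": np.asarray(out_ids)[order]},
        name="C",
    )
    return A_out, C_out


def unit_merge(
    A: xr.DataArray, C: xr.DataArray, thres_corr: float = 0.8
) -> tuple[xr.DataArray, xr.DataArray]:
    """Merge units that share footprint pixels and have correlated traces.

    Connected components of the graph with edges (share >= 1 nonzero pixel)
    AND (trace Pearson correlation > thres_corr) merge to footprint sum and
    trace mean.  Applied between CNMF iterations only, never after the final
    temporal update.
    """
    nunit = A.sizes["unit"]
    if nunit <= 1:
        return A, C
    sup = csr_matrix(A.values.reshape(nunit, -1) > 0)
    share = (sup @ sup.T).toarray() > 0
    Cv = C.values.astype(np.float64)
    Cd = Cv - Cv.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cd, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Cd @ Cd.T) / np.outer(norms, norms)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.triu(share & (corr > thres_corr), k=1)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return _merge_components(A, C, labels)


def apply_unit_labels(
    model: CNMFModel, labels: Sequence[object]
) -> CNMFModel:
    """Apply curation labels: 'keep', 'drop', or an int merge-group id.

    Units sharing a group id merge with the same semantics as
    :func:`unit_merge`; the input model is never modified.
    """
    unit_ids = model.unit_ids
    if len(labels) != len(unit_ids):
        raise ValueError("one label per unit required")
    keep_pos, group_of = [], {}
    for pos, lab in enumerate(labels):
        if lab == "drop":
            continue
        keep_pos.append(pos)
        if lab != "keep":
            group_of[pos] = lab
    if not keep_pos:
        raise ValueError("all units dropped")
    keep_pos = np.asarray(keep_pos)
    A = model.A.isel(unit=keep_pos)
    C = model.C.isel(unit=keep_pos)
    S = model.S.isel(unit=keep_pos) if model.S is not None else None
    merge_labels = np.arange(len(keep_pos))
    groups: dict[object, list[int]] = {}
    for i, pos in enumerate(keep_pos):
        if pos in group_of:
            groups.setdefault(group_of[pos], []).append(i)
    for members in groups.values():
        merge_labels[members] = members[0]
    A_out, C_out = _merge_components(A, C, merge_labels)
    if S is not None:
        _, S_out = _merge_components(A, S, merge_labels)
        S_out = S_out.rename("S")
    else:
        S_out = None
    return CNMFModel(A=A_out, C=C_out, b=model.b.copy(), f=model.f.copy(), S=S_out)


def unit_table(fits: dict[int, TemporalFit]) -> pd.DataFrame:
    """Per-unit diagnostics table (id, b0, c0, scale, AR coefficients)."""
    rows = []
    for uid, fit in sorted(fits.items()):
        coefs = dict(zip(("g1", "g2"), fit.ar.coefs))
        rows.append(
            {"unit_id": uid, "b0": fit.b0, "c0": fit.c0, "scale": fit.scale,
             "ar_order": fit.ar.order, "noise_sd": fit.ar.noise_sd, **coefs}
        )
    return pd.DataFrame(rows)
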