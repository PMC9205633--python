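"""Accuracy metrics against ground truth (or a second pipeline's output).

Estimated units are matched one-to-one to reference units by minimizing the
total footprint-centroid distance (optimal assignment), pairs beyond a
distance cutoff are discarded, and detection quality is summarized as
precision / recall / F1 plus median Pearson correlations of matched
footprints and traces.  Deconvolved spike signals are compared after
temporal binning, since a real-valued deconvolution and binary ground-truth
spikes only agree up to local timing jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.optimize import linear_sum_assignment

from .crossreg import calculate_centroids


@dataclass
class MatchResult:
    """One-to-one unit pairing; rows are positions on the unit axes."""

    pairs: list[tuple[int, int, float]]  # (truth position, est position, distance)
    n_true: int
    n_est: int

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_neurons(
    A_true: xr.DataArray, A_est: xr.DataArray, max_dist: float = 8.0
) -> MatchResult:
    """Optimal centroid assignment between unit sets, cut at ``max_dist`` px."""
    n_true, n_est = A_true.sizes["unit"], A_est.sizes["unit"]
    if n_true == 0 or n_est == 0:
        return MatchResult([], n_true, n_est)
    ct = calculate_centroids(A_true)[["row", "col"]].to_numpy()
    ce = calculate_centroids(A_est)[["row", "col"]].to_numpy()
    dist = np.linalg.norm(ct[:, None, :] - ce[None, :, :], axis=-1)
    # forbid over-threshold assignments with a large finite cost so the
    # assignment stays feasible, then drop them from the result
    cost = np.where(dist <= max_dist, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= max_dist
    ]
    return MatchResult(pairs, n_true, n_est)


def score_f1(match: MatchResult) -> tuple[float, float, float]:
    """precision = matched/est, recall = matched/true, f1 = harmonic mean."""
    if match.n_est == 0 and match.n_true == 0:
        raise ValueError("undefined: no estimated and no true units")
    precision = match.n_matched / match.n_est if match.n_est else 0.0
    recall = match.n_matched / match.n_true if match.n_true else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.linalg.norm(xd) * np.linalg.norm(yd)
    return float(xd @ yd / denom) if denom > 0 else np.nan


def median_correlations(
    match: MatchResult,
    A_true: xr.DataArray,
    A_est: xr.DataArray,
    C_true: xr.DataArray,
    C_est: xr.DataArray,
) -> tuple[float, float]:
    """Median Pearson correlation of matched footprints and matched traces.

    Zero-variance members give an undefined correlation and are excluded
    with a warning.
    """
    if match.n_matched == 0:
        raise ValueError("no matched pairs")
    fp_corrs, tr_corrs = [], []
    for i, j, _ in match.pairs:
        fp = _pearson(A_true.values[i], A_est.values[j])
        tr = _pearson(C_true.values[i], C_est.values[j])
        if np.isnan(fp) or np.isnan(tr):
            warnings.warn(f"excluding pair ({i}, {j}) with zero-variance member")
            continue
        fp_corrs.append(fp)
        tr_corrs.append(tr)
    return float(np.median(fp_corrs)), float(np.median(tr_corrs))


def _bin_sum(x: np.ndarray, factor: int) -> np.ndarray:
    n = (x.shape[-1] // factor) * factor
    return x[..., :n].reshape(*x.shape[:-1], n // factor, factor).sum(axis=-1)


def spike_correlation(
    S_true: xr.DataArray,
    S_est: xr.DataArray,
    match: MatchResult,
    factor: int = 5,
) -> tuple[np.ndarray, float, float]:
    """Per-matched-unit Pearson correlation of ``factor``-binned spike signals.

    Returns (per-unit correlations, mean, sd); zero-variance binned series
    are excluded with a warning.
    """
    if S_true.sizes["frame"] != S_est.sizes["frame"]:
        raise ValueError("frame counts differ")
    corrs = []
    for i, j, _ in match.pairs:
        st = _bin_sum(S_true.values[i], factor)
        se = _bin_sum(S_est.values[j], factor)
        r = _pearson(st, se)
        if np.isnan(r):
            warnings.warn(f"excluding pair ({i}, {j}) with zero-variance binned series")
            continue
        corrs.append(r)
    corrs = np.asarray(corrs)
    return corrs, float(corrs.mean()), float(corrs.std())
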