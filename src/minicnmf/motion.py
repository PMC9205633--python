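"""Rigid translational motion correction.

Shifts are estimated by maximizing the normalized cross-correlation between
each frame and a template over an integer shift window, organised in a
divide-and-conquer recursion: frames inside a leaf chunk are registered to
the chunk's middle frame, then chunks are merged in groups of three using
max projections of the already-registered frames as templates (so the
temporally stable cellular activity, not single noisy frames, anchors the
alignment).  Whenever the max-projection estimate disagrees with the shift
between the two consecutive frames bordering the chunks by more than
``fallback_thres`` pixels on either axis, the consecutive-frame estimate is
used instead — this guards against pathological max projections when
activity differs across chunks.

Only integer-pixel shifts are estimated and applied (no interpolation).
Estimates are reported relative to the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from skimage.feature import match_template

from .core_io import CropMask


def _translate(frame: np.ndarray, by: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """Move frame content by integer (dy, dx); vacated borders take ``fill``."""
    dy, dx = int(by[0]), int(by[1])
    out = np.full_like(frame, fill)
    h, w = frame.shape
    if abs(dy) >= h or abs(dx) >= w:
        return out
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = frame[src_y, src_x]
    return out


def match_template_shift(
    frame: np.ndarray, template: np.ndarray, max_shift: int
) -> tuple[int, int]:
    """Integer shift of ``frame`` relative to ``template`` maximizing NCC.

    Searches ``[-max_shift, max_shift]^2``; the correlation at shift
    ``(dy, dx)`` is computed between the template interior (cropped by
    ``max_shift``) and the equally-sized frame window offset by the shift.
    Ties are broken toward the smallest L-infinity shift, then row before
    column.
    """
    frame = np.asarray(frame, dtype=np.float32)
    template = np.asarray(template, dtype=np.float32)
    if frame.shape != template.shape:
        raise ValueError("frame and template must share a shape")
    if frame.std() == 0 or template.std() == 0:
        raise ValueError("flat image: zero-variance input to registration")
    m = int(max_shift)
    if m < 0:
        raise ValueError("max_shift must be >= 0")
    if m == 0:
        return (0, 0)
    h, w = frame.shape
    if 2 * m >= h or 2 * m >= w:
        raise ValueError(f"max_shift {m} too large for frame of shape {frame.shape}")
    core = template[m : h - m, m : w - m]
    if core.std() == 0:
        raise ValueError("flat image: zero-variance template interior")
    corr = match_template(frame, core, pad_input=False)  # (2m+1, 2m+1)
    best = float(corr.max())
    cand = np.argwhere(corr >= best - 1e-9)
    shifts = cand - m  # row of corr -> dy, col -> dx
    order = np.lexsort((shifts[:, 1], shifts[:, 0], np.abs(shifts).max(axis=1)))
    dy, dx = shifts[order[0]]
    return (int(dy), int(dx))


def _match_or_zero(frame, template, max_shift) -> tuple[int, int]:
    """Registration step that treats degenerate pairs as evidence of no motion."""
    try:
        return match_template_shift(frame, template, max_shift)
    except ValueError:
        return (0, 0)


@dataclass
class _Chunk:
    shifts: np.ndarray  # (n, 2) per-frame shifts relative to this chunk's reference
    start: int  # global index of first frame
    maxproj: np.ndarray  # max projection of registered frames
    first_reg: np.ndarray  # registered first frame
    last_reg: np.ndarray  # registered last frame


def _register_leaf(frames: np.ndarray, start: int, max_shift: int) -> _Chunk:
    n = len(frames)
    mid = n // 2
    template = frames[mid]
    shifts = np.zeros((n, 2), dtype=int)
    maxproj = np.full(frames.shape[1:], -np.inf, dtype=np.float32)
    regs = {}
    for t in range(n):
        if t != mid:
            shifts[t] = _match_or_zero(frames[t], template, max_shift)
        reg = _translate(frames[t], -shifts[t])
        np.maximum(maxproj, reg, out=maxproj)
        if t in (0, n - 1):
            regs[t] = reg
    return _Chunk(shifts, start, maxproj, regs.get(0, regs[n - 1]), regs[n - 1])


def _offset_chunk(chunk: _Chunk, offset: np.ndarray) -> _Chunk:
    """Re-express a chunk in a reference displaced by ``offset``."""
    if not offset.any():
        return chunk
    return _Chunk(
        shifts=chunk.shifts + offset,
        start=chunk.start,
        maxproj=_translate(chunk.maxproj, tuple(-offset)),
        first_reg=_translate(chunk.first_reg, tuple(-offset)),
        last_reg=_translate(chunk.last_reg, tuple(-offset)),
    )


def _merge_group(
    group: list[_Chunk], max_shift: int, fallback_thres: float
) -> _Chunk:
    mid = len(group) // 2
    ref = group[mid]
    registered = []
    for i, chunk in enumerate(group):
        if i == mid:
            registered.append(chunk)
            continue
        off_mp = np.array(_match_or_zero(chunk.maxproj, ref.maxproj, max_shift))
        # consecutive frames bordering the two chunks, both already registered
        # within their own chunk, estimate the same inter-chunk offset
        if i < mid:
            earlier, later = chunk, group[i + 1]
        else:
            earlier, later = group[i - 1], chunk
        off_cons_pair = np.array(
            _match_or_zero(earlier.last_reg, later.first_reg, max_shift)
        )
        # translate the pairwise estimate into "chunk relative to ref"
        if i < mid:
            off_cons = off_cons_pair if i + 1 == mid else off_cons_pair + np.array(
                _match_or_zero(group[i + 1].maxproj, ref.maxproj, max_shift)
            )
        else:
            off_cons = -off_cons_pair if i - 1 == mid else -off_cons_pair + np.array(
                _match_or_zero(group[i - 1].maxproj, ref.maxproj, max_shift)
            )
        use = off_cons if np.abs(off_mp - off_cons).max() > fallback_thres else off_mp
        registered.append(_offset_chunk(chunk, use))
    registered.sort(key=lambda c: c.start)
    shifts = np.concatenate([c.shifts for c in registered])
    maxproj = np.max([c.maxproj for c in registered], axis=0)
    return _Chunk(shifts, registered[0].start, maxproj,
                  registered[0].first_reg, registered[-1].last_reg)


def estimate_motion(
    video: xr.DataArray,
    chunk_nfm: int = 3,
    max_shift: int = 20,
    fallback_thres: float = 5.0,
    mask: CropMask | None = None,
) -> np.ndarray:
    """Per-frame integer rigid shifts ``(dy, dx)``, relative to the first frame.

    ``chunk_nfm`` is the leaf chunk length of the recursion (chunk counts then
    shrink by a factor of three per level).  ``mask`` restricts estimation to
    a subregion, e.g. to avoid anchored artifacts.
    """
    if int(chunk_nfm) < 2:
        raise ValueError("chunk_nfm must be >= 2")
    nfm = video.sizes["frame"]
    if nfm == 0:
        raise ValueError("empty input: video has no frames")
    data = video.values
    if mask is not None:
        mask.validate(*data.shape[1:])
        data = data[:, slice(*mask.row), slice(*mask.col)]
    if nfm == 1:
        return np.zeros((1, 2), dtype=int)
    # keep the template core at least half the frame: a search window much
    # larger than the frame leaves too few pixels to correlate reliably
    m_eff = max(1, min(int(max_shift), (min(data.shape[1:]) - 1) // 4))
    chunks = [
        _register_leaf(data[s : s + chunk_nfm], s, m_eff)
        for s in range(0, nfm, int(chunk_nfm))
        if s < nfm
    ]
    # a trailing chunk of one frame cannot self-register; keep it, the merge
    # step aligns it via its (identical) maxproj / border frame
    while len(chunks) > 1:
        merged = []
        for i in range(0, len(chunks), 3):
            group = chunks[i : i + 3]
            merged.append(group[0] if len(group) == 1 else _merge_group(group, m_eff, fallback_thres))
        chunks = merged
    shifts = chunks[0].shifts - chunks[0].shifts[0]
    return np.clip(shifts, -int(max_shift), int(max_shift))


def apply_shifts(
    video: xr.DataArray, shifts: np.ndarray, fill: float = 0.0
) -> xr.DataArray:
    """Undo estimated motion by translating each frame by ``-shift``."""
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (video.sizes["frame"], 2):
        raise ValueError(
            f"shifts of shape {shifts.shape} do not match {video.sizes['frame']} frames"
        )
    data = video.values
    out = np.empty_like(data)
    for t in range(len(data)):
        out[t] = _translate(data[t], tuple(-shifts[t]), fill=fill)
    res = video.copy(data=out)
    res.attrs = dict(video.attrs)
    return res
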