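"""Video ingestion, downsampling, chunked persistence, and the shared data model.

The in-memory container for video data is an :class:`xarray.DataArray` with
dims ``("frame", "height", "width")``, non-negative float32 values on the raw
8-bit scale (0-255 for miniscope AVI/TIFF input), and a ``fps`` attribute.
Model arrays (footprints, traces) use the same convention with a leading
``unit`` dim.  On-disk persistence uses Zarr via the xarray backend; chunked
execution is expressed as a per-axis chunk plan stored in ``attrs`` and
consumed by the block loops inside each pipeline stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import xarray as xr

VIDEO_DIMS = ("frame", "height", "width")

#: attrs key under which a chunk plan is recorded by :func:`rechunk`
CHUNK_ATTR = "chunk_plan"


@dataclass(frozen=True)
class CropMask:
    """Half-open pixel intervals ``[start, stop)`` selecting a rectangular region."""

    row: tuple[int, int]
    col: tuple[int, int]

    def validate(self, height: int, width: int) -> None:
        r0, r1 = self.row
        c0, c1 = self.col
        if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
            raise ValueError(
                f"bounds error: mask rows {self.row} cols {self.col} outside "
                f"frame of shape ({height}, {width})"
            )


def video_array(
    data: np.ndarray,
    fps: float = 30.0,
    *,
    frame_offset: int = 0,
    name: str = "video",
) -> xr.DataArray:
    """Wrap a 3-D ``(frame, height, width)`` array in the shared video container."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D (frame, height, width) data, got {data.ndim}-D")
    if data.dtype.kind not in "fiu":
        raise TypeError(f"unsupported dtype {data.dtype}")
    arr = xr.DataArray(
        data.astype(np.float32, copy=False),
        dims=VIDEO_DIMS,
        coords={
            "frame": np.arange(frame_offset, frame_offset + data.shape[0]),
            "height": np.arange(data.shape[1]),
            "width": np.arange(data.shape[2]),
        },
        name=name,
        attrs={"fps": float(fps)},
    )
    return arr


def validate_video(video: xr.DataArray) -> None:
    """Check the VideoArray invariants: dims, non-negativity, monotone frames."""
    if tuple(video.dims) != VIDEO_DIMS:
        raise ValueError(f"axis names must be {VIDEO_DIMS}, got {tuple(video.dims)}")
    if float(video.min()) < 0:
        raise ValueError("video contains negative values")
    fr = video.coords["frame"].values
    if fr.size and np.any(np.diff(fr) <= 0):
        raise ValueError("frame coordinate must be strictly increasing")


def natural_sort(names: list[str]) -> list[str]:
    """Sort filenames with embedded integers in numeric order (msCam2 < msCam10)."""

    def key(name: str):
        return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]

    return sorted(names, key=key)


def _read_frames(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    elif suffix == ".avi":
        try:
            import imageio.v3 as iio

            data = iio.imread(path)
        except Exception as exc:  # no decodable backend for this container
            raise ValueError(f"format error: cannot decode {path.name}: {exc}") from exc
    else:
        raise ValueError(f"format error: unsupported container {path.suffix!r}")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:  # RGB(A): take channel 0 per convention
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"format error: {path.name} is not a grayscale frame stack")
    return data


def _downsample_axis(
    data: np.ndarray, axis: int, factor: int, strategy: str
) -> np.ndarray:
    if factor <= 1:
        return data
    if strategy == "subset":
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(None, None, factor)
        return data[tuple(sl)]
    if strategy == "mean":
        # trailing remainder on a non-divisible axis is dropped
        n = (data.shape[axis] // factor) * factor
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(0, n)
        trimmed = data[tuple(sl)]
        shape = list(trimmed.shape)
        shape[axis : axis + 1] = [n // factor, factor]
        return trimmed.reshape(shape).mean(axis=axis + 1)
    raise ValueError(f"unknown downsampling strategy {strategy!r}")


def load_videos(
    path: str | Path,
    pattern: str = "*.tif",
    downsample: Mapping[str, int] | None = None,
    strategy: str = "subset",
    fps: float = 30.0,
) -> xr.DataArray:
    """Load all files matching ``pattern`` under ``path`` into one VideoArray.

    Files are concatenated in natural filename order, then optionally
    downsampled per axis (``{"frame": 2, "height": 2, ...}``) by strided
    subsetting or interval means.  Values are promoted to float32 but kept on
    the raw 8-bit scale.
    """
    path = Path(path)
    files = [path / name for name in natural_sort([p.name for p in path.glob(pattern)])]
    if not files:
        raise FileNotFoundError(f"empty input: no file matches {pattern!r} in {path}")
    stacks = [_read_frames(f) for f in files]
    shapes = {s.shape[1:] for s in stacks}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: frame shapes {sorted(shapes)} differ across files")
    data = np.concatenate(stacks, axis=0).astype(np.float32)
    ds_fps = fps
    if downsample:
        for ax_name, factor in downsample.items():
            if ax_name not in VIDEO_DIMS:
                raise ValueError(f"unknown axis {ax_name!r}")
            data = _downsample_axis(data, VIDEO_DIMS.index(ax_name), int(factor), strategy)
        if downsample.get("frame", 1) > 1:
            ds_fps = fps / downsample["frame"]
    return video_array(data, fps=ds_fps)


def parse_path_metadata(path: str | Path, mapping: Mapping[str, int]) -> dict[str, str]:
    """Pull session metadata (animal, group, date, ...) out of a directory path.

    ``mapping`` assigns each metadata key the index of a path component,
    counted from the end (0 = the session folder itself, 1 = its parent...),
    e.g. ``{"session": 0, "animal": 1}`` for ``.../mouse3/2021_06_01``.
    """
    parts = Path(path).parts
    out = {}
    for key, idx in mapping.items():
        if not 0 <= int(idx) < len(parts):
            raise ValueError(f"path component {idx} for {key!r} outside {path}")
        out[key] = parts[-1 - int(idx)]
    return out


def subset_video(
    video: xr.DataArray,
    frames: tuple[int, int] | None = None,
    mask: CropMask | None = None,
) -> xr.DataArray:
    """Pure slicing by a frame interval ``[start, stop)`` and/or a crop mask."""
    nfm, height, width = video.shape
    out = video
    if frames is not None:
        f0, f1 = frames
        if not (0 <= f0 < f1 <= nfm):
            raise ValueError(f"bounds error: frame interval {frames} outside [0, {nfm})")
        out = out.isel(frame=slice(f0, f1))
    if mask is not None:
        mask.validate(height, width)
        out = out.isel(height=slice(*mask.row), width=slice(*mask.col))
    return out


def persist_array(array: xr.DataArray, store_path: str | Path) -> Path:
    """Write an array to a Zarr store; round-trips bit-exactly via :func:`load_array`."""
    store_path = Path(store_path)
    name = array.name or "data"
    array.to_dataset(name=name).to_zarr(store_path, mode="w")
    return store_path


def load_array(store_path: str | Path) -> xr.DataArray:
    store_path = Path(store_path)
    ds = xr.open_zarr(store_path)
    names = list(ds.data_vars)
    if len(names) != 1:
        raise ValueError(f"expected a single array in {store_path}, found {names}")
    arr = ds[names[0]].load()
    ds.close()
    return arr


def rechunk(array: xr.DataArray, chunk_plan: Mapping[str, int]) -> xr.DataArray:
    """Record a per-axis chunk plan; values are untouched.

    The plan only directs how block loops inside the pipeline stages split
    their work, so any plan yields identical results.
    """
    for dim, size in chunk_plan.items():
        if dim not in array.dims:
            raise ValueError(f"unknown axis {dim!r}")
        if int(size) < 1:
            raise ValueError("chunk sizes must be >= 1")
    out = array.copy(deep=False)
    out.attrs = dict(array.attrs)
    out.attrs[CHUNK_ATTR] = {d: int(s) for d, s in chunk_plan.items()}
    return out


def chunk_size(array: xr.DataArray, dim: str, default: int | None = None) -> int:
    """Chunk length along ``dim`` from the recorded plan (whole axis if absent)."""
    plan = array.attrs.get(CHUNK_ATTR, {})
    n = array.sizes[dim]
    return int(min(n, plan.get(dim, default if default is not None else n))) or 1


def iter_blocks(n: int, size: int) -> Iterator[slice]:
    """Yield consecutive slices covering ``range(n)`` in blocks of ``size``."""
    size = max(1, int(size))
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))
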