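"""Config-driven end-to-end orchestration.

A single :class:`PipelineConfig` carries every stage parameter (validated up
front), and :func:`run_pipeline` executes preprocess -> motion correction ->
seed initialization -> (spatial update -> temporal update) x ``iters`` with
cell merging between iterations but never after the final temporal update.
Every intermediate can be persisted to a Zarr store, and a machine-readable
JSON report records parameters, per-stage unit counts, and timings.

Window-size defaults follow the expected-cell-size heuristic the stages
document (median window ~ cell radius; morphology, local-max, similarity,
and dilation windows ~ cell diameter) evaluated at the simulator's default
cell scale (~10 px diameter).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import xarray as xr
import yaml

from . import cnmf as cnmf_mod
from . import initialization as init_mod
from . import motion as motion_mod
from . import preprocessing as prep_mod
from .core_io import load_videos, persist_array
from .cnmf import CNMFModel
from .simulation import simulate_miniscope

logger = logging.getLogger("minicnmf")


@dataclass
class PipelineConfig:
    # input: either a directory of videos, or simulator parameters
    input_path: str | None = None
    input_pattern: str = "*.tif"
    fps: float = 30.0
    downsample: dict[str, int] | None = None
    downsample_strategy: str = "subset"
    simulate: dict[str, Any] | None = None
    output_dir: str | None = None
    seed: int = 0
    # preprocessing
    denoise_wnd: int = 5
    background_wnd: int = 10
    # motion correction
    chunk_nfm: int = 3
    max_shift: int = 20
    fallback_thres: float = 5.0
    # seed initialization
    wnd_size: int = 1000
    step_size: int = 200
    seed_method: str = "rolling"
    n_iter: int = 10
    max_wnd: int = 6
    diff_thres: float = 3.0
    noise_freq: float = 1.0
    pnr_thres: float = 1.0
    ks_sig: float = 0.05
    merge_dist: float = 8.0
    merge_corr: float = 0.8
    sim_thres: float = 0.5
    init_wnd: int = 10
    # CNMF
    dl_wnd: int = 10
    sparse_penalty_spatial: float = 0.1
    sparse_penalty_temporal: float = 0.008
    ar_order: int = 2
    jac_thres: float = 0.2
    unit_merge_corr: float = 0.8
    iters: int = 2
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input_path is None and self.simulate is None:
            raise ValueError("config needs input_path or simulate parameters")
        if self.denoise_wnd < 1 or self.denoise_wnd % 2 == 0:
            raise ValueError("denoise_wnd must be odd and >= 1")
        if self.background_wnd < 1:
            raise ValueError("background_wnd must be >= 1")
        if self.chunk_nfm < 2:
            raise ValueError("chunk_nfm must be >= 2")
        if not 0 < self.noise_freq < self.fps / 2:
            raise ValueError("noise_freq must lie in (0, fps/2)")
        if self.ar_order not in (1, 2):
            raise ValueError("ar_order must be 1 or 2")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        for name in ("sparse_penalty_spatial", "sparse_penalty_temporal",
                     "pnr_thres", "merge_dist", "diff_thres"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_input(config: PipelineConfig) -> xr.DataArray:
    if config.simulate is not None:
        params = dict(config.simulate)
        params.setdefault("seed", config.seed)
        params.setdefault("fps", config.fps)
        return simulate_miniscope(**params).video
    return load_videos(
        config.input_path,
        config.input_pattern,
        downsample=config.downsample,
        strategy=config.downsample_strategy,
        fps=config.fps,
    )


def run_stages(
    video: xr.DataArray, config: PipelineConfig
) -> tuple[CNMFModel, dict[str, Any]]:
    """Run every stage on an in-memory video; returns (model, report)."""
    config.validate()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": dataclasses.asdict(config),
        "unit_counts": {},
        "timings": {},
    }

    def _persist(arr: xr.DataArray, name: str) -> None:
        if out_dir is not None:
            persist_array(arr.rename(name), out_dir / f"{name}.zarr")

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                report["timings"][name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    report["failed_stage"] = name
                    if out_dir is not None:
                        (out_dir / "report.json").write_text(
                            json.dumps(report, indent=2, default=str)
                        )
                else:
                    logger.info(
                        "stage %s done in %.1fs", name, report["timings"][name]
                    )
                return False

        return _Timer()

    with _stage("preprocess"):
        clean = prep_mod.preprocess(
            video, denoise_wnd=config.denoise_wnd, background_wnd=config.background_wnd
        )
        _persist(clean, "preprocessed")

    with _stage("motion"):
        shifts = motion_mod.estimate_motion(
            clean,
            chunk_nfm=config.chunk_nfm,
            max_shift=config.max_shift,
            fallback_thres=config.fallback_thres,
        )
        registered = motion_mod.apply_shifts(clean, shifts)
        report["max_abs_shift"] = int(np.abs(shifts).max())
        _persist(registered, "registered")

    with _stage("initialize"):
        seeds = init_mod.seeds_init(
            registered,
            wnd_size=config.wnd_size,
            step_size=config.step_size,
            method=config.seed_method,
            n_iter=config.n_iter,
            max_wnd=config.max_wnd,
            diff_thres=config.diff_thres,
            seed=config.seed,
        )
        report["unit_counts"]["seeds_init"] = len(seeds)
        seeds = init_mod.pnr_refine(
            registered, seeds, noise_freq=config.noise_freq, thres=config.pnr_thres
        )
        report["unit_counts"]["seeds_pnr"] = len(init_mod.active_seeds(seeds))
        seeds = init_mod.ks_refine(registered, seeds, sig=config.ks_sig)
        report["unit_counts"]["seeds_ks"] = len(init_mod.active_seeds(seeds))
        seeds = init_mod.seeds_merge(
            registered,
            seeds,
            thres_dist=config.merge_dist,
            thres_corr=config.merge_corr,
            noise_freq=config.noise_freq,
        )
        report["unit_counts"]["seeds_merged"] = len(init_mod.active_seeds(seeds))
        if out_dir is not None:
            seeds.to_csv(out_dir / "seeds.csv", index=False)
        A = init_mod.init_spatial(
            registered, seeds, thres_corr=config.sim_thres, wnd=config.init_wnd
        )
        C = init_mod.init_temporal(registered, A)
        b, f = init_mod.init_background(registered, A, C)
        report["unit_counts"]["init"] = int(A.sizes["unit"])

    with _stage("noise"):
        sn = cnmf_mod.estimate_noise(registered, noise_freq=config.noise_freq)

    fits: dict[int, cnmf_mod.TemporalFit] = {}
    S = None
    for it in range(config.iters):
        with _stage(f"spatial_update_{it + 1}"):
            A, b, f = cnmf_mod.update_spatial(
                registered, A, C, b, f, sn,
                dl_wnd=config.dl_wnd,
                sparse_penalty=config.sparse_penalty_spatial,
            )
            C = C.sel(unit=A.coords["unit"].values)
            report["unit_counts"][f"spatial_{it + 1}"] = int(A.sizes["unit"])
        with _stage(f"temporal_update_{it + 1}"):
            A, C, S, fits = cnmf_mod.update_temporal(
                registered, A, C, b, f,
                p=config.ar_order,
                noise_freq=config.noise_freq,
                sparse_penalty=config.sparse_penalty_temporal,
                jac_thres=config.jac_thres,
            )
            report["unit_counts"][f"temporal_{it + 1}"] = int(A.sizes["unit"])
        if it < config.iters - 1:  # merge between iterations, never at the end
            with _stage(f"merge_{it + 1}"):
                A, C = cnmf_mod.unit_merge(A, C, thres_corr=config.unit_merge_corr)
                report["unit_counts"][f"merge_{it + 1}"] = int(A.sizes["unit"])

    model = CNMFModel(A=A, C=C, b=b, f=f, S=S)
    report["unit_counts"]["final"] = int(A.sizes["unit"])
    if out_dir is not None:
        for name, arr in (("A", A), ("C", C), ("S", S), ("b", b), ("f", f)):
            if arr is not None:
                persist_array(arr.rename(name), out_dir / f"{name}.zarr")
        cnmf_mod.unit_table(fits).to_csv(out_dir / "units.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
        config.to_yaml(out_dir / "config.yaml")
    return model, report


def run_pipeline(config: PipelineConfig) -> tuple[CNMFModel, dict[str, Any]]:
    """Load (or simulate) the input video and run every stage."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    video = _load_input(config)
    return run_stages(video, config)
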