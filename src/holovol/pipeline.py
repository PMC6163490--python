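"""End-to-end pipeline: simulate -> PSR -> phase recovery -> deconvolution.

Each stage writes its intermediates under the configured output directory
and the run returns a manifest listing every artifact with a checksum, the
per-stage wall time, and the parameters that produced it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import deconv, io, phase, psr, simulate
from .config import PipelineConfig

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - self.t0, 3)}
            return False

    return _Timer()


def _make_scene(cfg: PipelineConfig) -> simulate.SceneSpec:
    sc = cfg.scene
    pitch = cfg.optical.highres_pitch
    if sc.kind == "beads":
        return simulate.make_beads(
            n=sc.n,
            diameter=sc.diameter,
            z_planes=sc.z_planes,
            seed=cfg.seed,
            shape=tuple(sc.shape),
            pitch=pitch,
            noise_sigma=cfg.acquisition.noise_sigma,
        )
    if sc.kind == "bars":
        return simulate.make_bar_target(
            bar_widths=sc.bar_widths,
            seed=cfg.seed,
            shape=tuple(sc.shape),
            pitch=pitch,
            z=sc.z_planes[0],
            noise_sigma=cfg.acquisition.noise_sigma,
        )
    raise ValueError(f"unknown scene kind {sc.kind!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the artifact manifest.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written before the failure are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": [], "config": asdict(cfg), "seed": cfg.seed}
    z_heights = cfg.acquisition.z_list()

    with _stage(manifest, "simulate"):
        scene = _make_scene(cfg)
        stacks, _mh, _truth = simulate.acquire_multiheight(
            scene, cfg.optical, z_heights, seed=cfg.seed,
            noise_sigma=cfg.acquisition.noise_sigma,
        )
        for i, st in enumerate(stacks):
            io.save_stack(st, out / f"height_{i}", prefix="frame")

    with _stage(manifest, "psr"):
        highres = []
        for i, st in enumerate(stacks):
            hi = psr.synthesize_highres(st, cfg.optical.upsample_factor, deblur=True)
            highres.append(hi)
            p = io.save_image(hi, out / f"psr_height_{i}.tiff")
            _record(manifest, p, "psr")

    with _stage(manifest, "phase_recover"):
        mh = phase.MultiHeightSet(
            holograms=highres, z_nominal=z_heights, pitch=cfg.optical.highres_pitch
        )
        if cfg.recovery.refine_z:
            phase.refine_heights(mh, wavelength=cfg.optical.wavelength)
        else:
            mh.z_refined = list(z_heights)
        hologram, report = phase.recover_phase(
            mh,
            wavelength=cfg.optical.wavelength,
            max_iter=cfg.recovery.max_iter,
            tol=cfg.recovery.tol,
            init_phase=cfg.recovery.init_phase,
            seed=cfg.seed,
        )
        p = io.save_complex_field(hologram, out / "hologram_complex.tiff")
        _record(manifest, p, "phase_recover")
        (out / "recovery_report.json").write_text(
            json.dumps(
                {
                    "iterations_run": report.iterations_run,
                    "residual_history": report.residual_history,
                    "converged": report.converged,
                    "z_refined": mh.z_refined,
                },
                indent=2,
            )
        )

    with _stage(manifest, "backpropagate"):
        z_vol = np.asarray(cfg.deconvolution.z_values())
        measured = deconv.build_measured_volume(hologram, z_vol, mode=cfg.deconvolution.mode)
        p = io.save_volume(measured, out / "volume_stacked.tiff", {"stage": "backpropagate"})
        _record(manifest, p, "backpropagate")

    with _stage(manifest, "deconvolve"):
        scattered = deconv.build_measured_volume(
            hologram, z_vol, mode=cfg.deconvolution.mode, background="dc"
        )
        psf = deconv.simulate_psf(
            cfg.optical,
            measured.shape[1:],
            z_vol,
            source_kind=cfg.deconvolution.source_kind,
            mode=cfg.deconvolution.mode,
        )
        if cfg.deconvolution.method == "gold":
            recovered, residuals = deconv.gold_deconvolve(
                scattered, psf, beta=cfg.deconvolution.beta, n_iter=cfg.deconvolution.n_iter
            )
        elif cfg.deconvolution.method == "wiener":
            recovered = deconv.wiener_deconvolve(scattered, psf, beta=cfg.deconvolution.beta)
            residuals = []
        else:
            raise ValueError(f"unknown deconvolution method {cfg.deconvolution.method!r}")
        p = io.save_volume(
            recovered,
            out / "volume_deconvolved.tiff",
            {
                "stage": "deconvolve",
                "method": cfg.deconvolution.method,
                "beta": cfg.deconvolution.beta,
                "residual_history": residuals,
            },
        )
        _record(manifest, p, "deconvolve")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _record(manifest: dict, path: Path, stage: str) -> None:
    manifest["artifacts"].append(
        {"path": str(path), "stage": stage, "sha256": io.sha256_of(path)}
    )
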