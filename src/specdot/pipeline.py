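"""Experiment orchestration: run pipeline stages from a config and write all
intermediate artifacts plus a machine-readable run log."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, phantoms, recon, spectra
from .calibrate import SystemCharacterization, calibrate_dataset
from .fem import MeasurementSet
from .meshing import TetMesh
from .profilometry import measure_height
from .recon import ReconSettings, reconstruct

__all__ = ["ExperimentConfig", "run_experiment", "StageError"]

STAGES = ("profile", "mesh", "simulate", "calibrate", "reconstruct")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class ExperimentConfig:
    """Declarative description of a synthetic experiment run."""

    stages: tuple = STAGES
    phantom: str = "block"  # 'block' or 'petri'
    resolution: float = 2.0
    petri_separation: float = 11.0
    petri_rotated: bool = False
    petri_compound: bool = False
    wavelengths: tuple | None = None
    exclude_wavelengths: tuple = ()
    noise_fraction: float = 0.0
    seed: int = 0
    optode_layout: str = "single_view"  # or detectors_3view / full_3view / petri
    pixel_size: float = 2.0
    reg_initial: float = 100.0
    tolerance: float = 0.02
    max_iterations: int = 30
    n_rel: float = 1.33
    characterization: dict | None = None  # {'sources': {...}, 'response': {...}}
    output_dir: str = "specdot_run"
    profile_height_mm: float = 20.0
    profile_image_px: int = 96
    verbose: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        if cfg.wavelengths is not None:
            cfg.wavelengths = tuple(float(l) for l in cfg.wavelengths)
        cfg.exclude_wavelengths = tuple(float(l) for l in cfg.exclude_wavelengths)
        return cfg

    def resolved_wavelengths(self) -> tuple:
        lams = self.wavelengths or tuple(sorted(spectra.SYSTEM_WAVELENGTHS))
        return tuple(l for l in lams
                     if not any(np.isclose(l, x) for x in self.exclude_wavelengths))


def _log(cfg: ExperimentConfig, msg: str) -> None:
    if cfg.verbose:
        print(f"[specdot] {msg}", file=sys.stderr)


def _build_phantom(cfg: ExperimentConfig):
    if cfg.phantom == "block":
        return phantoms.build_block_phantom(resolution=cfg.resolution)
    if cfg.phantom == "petri":
        return phantoms.build_petri_phantom(separation=cfg.petri_separation,
                                            rotated=cfg.petri_rotated,
                                            compound=cfg.petri_compound,
                                            resolution=cfg.resolution)
    raise StageError(f"mesh: unknown phantom kind {cfg.phantom!r}")


def _build_optodes(cfg: ExperimentConfig, mesh: TetMesh):
    if cfg.optode_layout == "single_view":
        return phantoms.single_view_optodes(mesh)
    if cfg.optode_layout == "petri":
        return phantoms.petri_optodes(mesh)
    if cfg.optode_layout == "detectors_3view":
        return phantoms.three_view_optodes(mesh, sources_three_views=False)
    if cfg.optode_layout == "full_3view":
        return phantoms.three_view_optodes(mesh, sources_three_views=True)
    raise StageError(f"simulate: unknown optode layout {cfg.optode_layout!r}")


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the requested stages, writing artifacts under the output dir.

    Stages build on each other; requesting a late stage without its inputs
    raises a :class:`StageError`.  The run log records settings, seed,
    package version and per-stage timings, so every run is reproducible.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError(f"config: unknown stages {sorted(unknown)}")
    timings = {}
    log = {"version": __version__, "seed": config.seed,
           "config": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(config).items()},
           "stages": list(stages)}
    phantom = None
    optodes = None
    data = None

    if "profile" in stages:
        t0 = time.perf_counter()
        h = np.full((config.profile_image_px, config.profile_image_px),
                    config.profile_height_mm)
        obj, ref, truth, calib = phantoms.synthesize_profilometry_scene(
            h, noise_sigma=0.0, seed=config.seed)
        hm = measure_height(obj, ref, calib, smoothing=None)
        io.save_height_map(hm, out / "height_map.txt")
        io.save_height_calibration(calib, out / "height_calibration.txt")
        timings["profile"] = time.perf_counter() - t0
        _log(config, f"profile: height map {hm.values.shape} written")

    if "mesh" in stages:
        t0 = time.perf_counter()
        phantom = _build_phantom(config)
        io.save_mesh(phantom.mesh, out / "phantom")
        io.export_mesh_vtk(phantom.mesh, out / "phantom.vtk")
        timings["mesh"] = time.perf_counter() - t0
        _log(config, f"mesh: {phantom.mesh.n_nodes} nodes, "
                     f"{phantom.mesh.n_elements} elements")

    if "simulate" in stages:
        if phantom is None:
            raise StageError("simulate: no mesh artifact; run the 'mesh' stage first")
        t0 = time.perf_counter()
        optodes = _build_optodes(config, phantom.mesh)
        data = phantoms.simulate_phantom_data(
            phantom, optodes, wavelengths=config.resolved_wavelengths(),
            noise_fraction=config.noise_fraction, seed=config.seed,
            n_rel=config.n_rel)
        io.save_measurements(data, out / "measurements.csv")
        timings["simulate"] = time.perf_counter() - t0
        _log(config, f"simulate: {len(data)} amplitudes written")

    calibrated = data
    if "calibrate" in stages:
        if data is None or phantom is None or optodes is None:
            raise StageError("calibrate: no simulated data; run 'simulate' first")
        t0 = time.perf_counter()
        hom = phantoms.homogeneous_like(phantom)
        hom_data = phantoms.simulate_phantom_data(
            hom, optodes, wavelengths=config.resolved_wavelengths(),
            noise_fraction=config.noise_fraction, seed=config.seed + 1,
            n_rel=config.n_rel)
        if config.characterization:
            char = SystemCharacterization(
                {int(k): float(v) for k, v in config.characterization["sources"].items()},
                {float(k): float(v) for k, v in config.characterization["response"].items()})
        else:
            char = SystemCharacterization(
                {i: 1.0 for i in range(len(optodes.sources))},
                {l: 1.0 for l in config.resolved_wavelengths()})
        musp_prior = {
            lam: spectra.musp_from_mie(phantom.region_params[0].a,
                                       phantom.region_params[0].b, lam)
            for lam in config.resolved_wavelengths()}
        calibrated, calres = calibrate_dataset(
            data, hom_data, char, hom.mesh, optodes, musp_prior,
            n_rel=config.n_rel)
        io.save_measurements(calibrated, out / "measurements_calibrated.csv")
        calres.offsets.to_csv(out / "model_offsets.csv", index=False)
        with open(out / "bulk_properties.json", "w") as fh:
            json.dump({"mua": {str(k): v for k, v in calres.bulk_mua.items()},
                       "musp": {str(k): v for k, v in calres.bulk_musp.items()}},
                      fh, indent=2)
        timings["calibrate"] = time.perf_counter() - t0
        _log(config, f"calibrate: bulk mua {calres.bulk_mua}")

    if "reconstruct" in stages:
        if calibrated is None or phantom is None or optodes is None:
            raise StageError("reconstruct: no measurement artifact; run 'simulate' first")
        t0 = time.perf_counter()
        settings = ReconSettings(reg_initial=config.reg_initial,
                                 tolerance=config.tolerance,
                                 max_iterations=config.max_iterations,
                                 pixel_size=config.pixel_size,
                                 n_rel=config.n_rel)
        musp_by_lam = {
            lam: spectra.musp_from_mie(phantom.region_params[0].a,
                                       phantom.region_params[0].b, lam)
            for lam in config.resolved_wavelengths()}
        result = reconstruct(calibrated, phantom.mesh, optodes, phantom.table,
                             phantom.region_params[0], settings,
                             musp_by_wavelength=musp_by_lam)
        io.save_recon_result(result, out / "recon")
        timings["reconstruct"] = time.perf_counter() - t0
        _log(config, f"reconstruct: {result.n_iterations} iterations, "
                     f"converged={result.converged}")

    log["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
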