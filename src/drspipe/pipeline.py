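"""End-to-end orchestration: synth -> preprocess -> classification + MC depth.

A :class:`PipelineConfig` (YAML-loadable) drives the full run; every stage
seed is derived deterministically from the master seed and the stage name, so
stages are independently reproducible and the whole run is bit-identical under
a fixed configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, classify, io, mcdepth, synth
from .errors import ConfigError

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: a pure function of (master seed, stage)."""
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), key]).generate_state(1)[0])


@dataclass
class PipelineConfig:
    """Knobs for a full demo run; defaults complete in a few minutes."""

    seed: int = 0
    out_dir: str = "drs_run"
    grid_step: float = 4.0
    overlap: tuple = (1095.0, 1130.0)
    sdds: tuple = (630.0, 2500.0)
    n_patients: int = 7
    sites_per_patient: int = 15
    noise_sd: float = 0.02
    per_site_jitter_sd: float = 0.08
    per_patient_sd: float = 0.12
    contrast: float = 1.0
    cv_iterations: int = 10
    cv_folds: int = 2
    mc_photons: int = 100_000
    mc_wavelengths: tuple = (500.0, 700.0, 900.0, 1100.0, 1300.0, 1500.0,
                             1700.0, 1900.0)
    write_bundles: bool = False
    run_mc: bool = True
    run_kernel_table: bool = True
    run_range_table: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")
        if self.grid_step <= 0 or self.cv_iterations < 1 or self.cv_folds < 2:
            raise ConfigError("invalid grid_step / CV settings")
        if self.mc_photons < 1000:
            raise ConfigError("mc_photons must be >= 1000")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("overlap", "sdds", "mc_wavelengths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("overlap", "sdds", "mc_wavelengths"):
            d[key] = list(d[key])
        return d


@dataclass
class RunManifest:
    """Config snapshot plus content hashes of every output file."""

    config: dict
    version: str
    files: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), sort_keys=True,
                                   indent=1) + "\n", encoding="utf-8")
        return path


def _register(manifest: RunManifest, out_dir: Path, *paths) -> None:
    for p in paths:
        p = Path(p)
        manifest.files[str(p.relative_to(out_dir))] = io.sha256_file(p)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and write all artifacts plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    normal, tumor = synth.default_class_specs(
        contrast=config.contrast, n_patients=config.n_patients,
        sites_per_patient=config.sites_per_patient,
        per_site_jitter_sd=config.per_site_jitter_sd,
        per_patient_sd=config.per_patient_sd)

    for sdd in config.sdds:
        tag = f"sdd{int(sdd)}"
        t0 = time.time()
        stage = f"synth/{tag}"
        dataset, bundles = synth.generate_dataset(
            normal, tumor, sdd, noise_sd=config.noise_sd,
            seed=derive_seed(config.seed, stage),
            grid_step=config.grid_step, return_bundles=config.write_bundles)
        logger.info("stage=%s seed-derived n=%d wall=%.1fs", stage,
                    dataset.n_samples, time.time() - t0)
        p = io.write_dataset(out_dir / f"dataset_{tag}.csv", dataset)
        _register(manifest, out_dir, p, Path(str(p) + ".meta.json"))
        if config.write_bundles:
            bdir = out_dir / f"bundles_{tag}"
            for k, bundle in enumerate(bundles):
                io.write_bundle(bundle, bdir, f"site{k:04d}")

        if config.run_kernel_table:
            t0 = time.time()
            results = classify.kernel_comparison(
                dataset, n_iterations=config.cv_iterations,
                n_folds=config.cv_folds,
                seed=derive_seed(config.seed, f"kernels/{tag}"))
            p = io.write_results_table(out_dir / f"kernel_comparison_{tag}.csv",
                                       classify.results_table(results, "Type of SVM"))
            _register(manifest, out_dir, p)
            logger.info("stage=kernels/%s wall=%.1fs", tag, time.time() - t0)

        if config.run_range_table:
            t0 = time.time()
            results = classify.wavelength_range_experiment(
                dataset, n_iterations=config.cv_iterations,
                n_folds=config.cv_folds,
                seed=derive_seed(config.seed, f"ranges/{tag}"))
            p = io.write_results_table(
                out_dir / f"wavelength_ranges_{tag}.csv",
                classify.results_table(results, "Analyzed wavelengths"))
            _register(manifest, out_dir, p)
            logger.info("stage=ranges/%s wall=%.1fs", tag, time.time() - t0)

        if config.run_mc:
            t0 = time.time()
            model = synth._effective_model(normal, sdd)
            wl = np.asarray(config.mc_wavelengths, dtype=float)
            spectrum = synth.optical_properties(model, wl)
            props = [spectrum.at(w) for w in wl]
            profile = mcdepth.depth_profile(
                wl, props, sdd, n_photons=config.mc_photons,
                seed=derive_seed(config.seed, f"mcdepth/{tag}"))
            p = io.write_depth_profile(out_dir / f"depth_profile_{tag}.csv",
                                       profile)
            _register(manifest, out_dir, p, Path(str(p) + ".meta.json"))
            logger.info("stage=mcdepth/%s wall=%.1fs", tag, time.time() - t0)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    return manifest
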