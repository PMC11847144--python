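"""Experiment configuration: YAML schema, validation and orchestration.

A single YAML file describes one reproducible experiment: the phantom (a
named preset, an explicit feature geometry, or an HDF5 file), the banana
LUT (a file or build parameters), the scan pattern, ROA, camera and seeds.
``run_experiment`` executes the full pipeline and writes every artifact
plus a provenance manifest into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .banana import build_banana_lut
from .montecarlo import CameraModel
from .phantoms import dermis_properties, make_phantom
from .pipeline import PipelineConfig, run_pipeline, table1_phantom
from .rte import RTEModelConfig

__all__ = ["ExperimentConfig", "ConfigError", "validate_config",
           "default_config_dict", "run_experiment", "PHANTOM_PRESETS"]

# feature depth (mm) per preset; None = featureless, "sub" = buried cylinder
PHANTOM_PRESETS = {
    "d05": 0.5,
    "d1": 1.0,
    "d3": 3.0,
    "d5": 5.0,
    "subsurface": "sub",
    "null": None,
}


class ConfigError(ValueError):
    """Invalid experiment configuration; the message lists every problem."""


_SCHEMA = {
    "phantom": {"preset": str, "path": str, "depth_mm": (int, float),
                "radius_mm": (int, float), "subsurface": bool,
                "depth_top_mm": (int, float)},
    "lut": {"path": str, "n_photons": int, "n_reps": int},
    "pattern": {"center_mm": list, "pitch_mm": (int, float),
                "points": list, "offsets_mm": list},
    "roa_side_mm": (int, float),
    "camera": {"gain": (int, float), "dark_offset": (int, float),
               "read_noise": (int, float), "bit_depth": int,
               "background_level": (int, float),
               "flatfield_amplitude": (int, float)},
    "acquisition": {"n_photons": int, "exposures_ms": list,
                    "n_replicates": int},
    "fit": {"rho_max": (int, float), "half_width": int, "g": (int, float)},
    "segmentation_k": (int, float),
    "calibration": str,
    "seeds": {"mc": int, "noise": int},
    "output_dir": str,
    "evaluate": bool,
}


@dataclass
class ExperimentConfig:
    """Validated, fully defaulted experiment description."""

    phantom: dict = field(default_factory=lambda: {"preset": "d1"})
    lut: dict = field(default_factory=lambda: {"n_photons": 100_000,
                                               "n_reps": 5})
    pattern: dict = field(default_factory=lambda: {
        "center_mm": [15.25, 15.25], "pitch_mm": 4.5, "points": [5, 5],
        "offsets_mm": [0.0, 0.0]})
    roa_side_mm: float = 12.0
    camera: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=lambda: {
        "n_photons": 100_000,
        "exposures_ms": [10.0, 20.0, 40.0, 80.0, 160.0],
        "n_replicates": 50})
    fit: dict = field(default_factory=dict)
    segmentation_k: float = 2.0
    calibration: str = "base_sampling"
    seeds: dict = field(default_factory=lambda: {"mc": 1234, "noise": 5678})
    output_dir: str = "mdoi_output"
    evaluate: bool = True

    def pipeline_config(self) -> PipelineConfig:
        rte_kwargs = {}
        if "rho_max" in self.fit:
            rte_kwargs["rho_max"] = float(self.fit["rho_max"])
        if "g" in self.fit:
            rte_kwargs["g"] = float(self.fit["g"])
        return PipelineConfig(
            roa_side_mm=float(self.roa_side_mm),
            grid_center_mm=tuple(self.pattern["center_mm"]),
            grid_pitch_mm=float(self.pattern["pitch_mm"]),
            grid_points=tuple(self.pattern["points"]),
            n_photons=int(self.acquisition["n_photons"]),
            exposures_ms=tuple(self.acquisition["exposures_ms"]),
            n_replicates=int(self.acquisition["n_replicates"]),
            camera=CameraModel(**self.camera),
            rte=RTEModelConfig(**rte_kwargs),
            fit_half_width=int(self.fit.get("half_width", 1)),
            segmentation_k=float(self.segmentation_k),
            lut_n_photons=int(self.lut.get("n_photons", 100_000)),
            lut_n_reps=int(self.lut.get("n_reps", 5)),
            mc_seed=int(self.seeds["mc"]),
            noise_seed=int(self.seeds["noise"]),
            calibration=self.calibration,
        )

    def build_phantom(self):
        if "path" in self.phantom:
            from .io import load_phantom
            return load_phantom(self.phantom["path"])
        if "preset" in self.phantom:
            depth = PHANTOM_PRESETS[self.phantom["preset"]]
            if depth is None:
                return make_phantom(bulk_props=dermis_properties(0.0))
            if depth == "sub":
                return table1_phantom(3.0, subsurface=True, depth_top_mm=1.0)
            return table1_phantom(float(depth))
        return table1_phantom(
            float(self.phantom.get("depth_mm", 1.0)),
            radius_mm=float(self.phantom.get("radius_mm", 2.0)),
            subsurface=bool(self.phantom.get("subsurface", False)),
            depth_top_mm=float(self.phantom.get("depth_top_mm", 1.0)),
        )


def _check_keys(data, schema, prefix, problems):
    for key, val in data.items():
        if key not in schema:
            problems.append(f"unknown key {prefix}{key}")
            continue
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                problems.append(f"{prefix}{key} must be a mapping")
            else:
                _check_keys(val, expect, f"{prefix}{key}.", problems)
        elif not isinstance(val, expect):
            problems.append(f"{prefix}{key} has wrong type "
                            f"({type(val).__name__})")


def validate_config(path_or_dict) -> ExperimentConfig:
    """Schema-check a YAML config and fill defaults.

    Raises :class:`ConfigError` listing every unknown key, wrong type or
    inconsistent combination found.
    """
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    problems: list[str] = []
    _check_keys(data, _SCHEMA, "", problems)
    phantom = data.get("phantom", {})
    if "preset" in phantom and phantom["preset"] not in PHANTOM_PRESETS:
        problems.append(
            f"phantom.preset must be one of {sorted(PHANTOM_PRESETS)}")
    if "lut" in data:
        lut = data["lut"]
        if "path" not in lut and "n_photons" not in lut:
            problems.append("lut needs either path or build parameters "
                            "(n_photons/n_reps)")
    if data.get("calibration") not in (None, "base_sampling",
                                       "uniform_phantom"):
        problems.append("calibration must be base_sampling or "
                        "uniform_phantom")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    cfg = ExperimentConfig()
    for key, val in data.items():
        cur = getattr(cfg, key)
        if isinstance(cur, dict) and isinstance(val, dict):
            cur.update(val)
        else:
            setattr(cfg, key, val)
    return cfg


def default_config_dict() -> dict:
    """The fully defaulted configuration as a plain dict (YAML-safe)."""
    return asdict(ExperimentConfig())


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured experiment; write artifacts + manifest.

    Outputs (HDF5 volumes, phantom, LUT, JSON report and manifest with
    config hash, package version, seeds and stage timings) land in
    ``config.output_dir``.  Reruns with identical seeds are bit-identical.
    """
    from .io import save_lut, save_phantom, save_volume

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    phantom = config.build_phantom()
    pcfg = config.pipeline_config()
    if "path" in config.lut:
        from .io import load_lut
        lut = load_lut(config.lut["path"])
    else:
        lut = build_banana_lut(phantom.bulk_properties(),
                               n_photons=pcfg.lut_n_photons,
                               n_reps=pcfg.lut_n_reps, seed=pcfg.mc_seed)
    result = run_pipeline(phantom, pcfg, lut=lut, evaluate=config.evaluate)

    save_phantom(out / "phantom.h5", phantom)
    save_lut(out / "lut.h5", lut)
    save_volume(out / "volume.h5", result.volume)
    save_volume(out / "relative.h5", result.relative)
    np.save(out / "segmentation.npy", result.segmentation)
    if result.report is not None:
        (out / "report.json").write_text(
            json.dumps(result.report.as_dict(), indent=2))
    cfg_dict = asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seeds": config.seeds,
        "timings_s": {**result.timings,
                      "total": time.perf_counter() - t_start},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
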