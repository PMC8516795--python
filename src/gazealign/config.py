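"""YAML/JSON run configuration and reproducibility logging."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import scipy
import yaml

from .elastic_core import AlgorithmParams
from .gaze_data import DEFAULT_GEOMETRY, ScreenGeometry

__all__ = ["ConfigError", "RunConfig", "load_config", "write_run_log"]

_PARAM_KEYS = ("w_p_deg", "w_d_deg", "epsilon_deg", "max_iter", "tol_deg")
_GEOM_KEYS = ("width_m", "height_m", "res_x", "res_y", "distance_m")


class ConfigError(ValueError):
    pass


class RunConfig:
    """Resolved configuration: geometry, algorithm parameters, map settings."""

    def __init__(
        self,
        geometry: ScreenGeometry = DEFAULT_GEOMETRY,
        params: AlgorithmParams = AlgorithmParams(),
        image_size: tuple[int, int] = (1024, 768),
        sigma_deg: float = 1.0,
        click_sigma_deg: float = 2.0,
    ) -> None:
        self.geometry = geometry
        self.params = params
        self.image_size = tuple(int(v) for v in image_size)
        self.sigma_deg = float(sigma_deg)
        self.click_sigma_deg = float(click_sigma_deg)

    def to_dict(self) -> dict:
        return {
            "geometry": asdict(self.geometry),
            "params": asdict(self.params),
            "image_size": list(self.image_size),
            "sigma_deg": self.sigma_deg,
            "click_sigma_deg": self.click_sigma_deg,
        }


def load_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file plus
    keyword overrides (flags win over the file).

    If the file contains a ``params`` or ``geometry`` block, that block must
    be complete; a missing key raises :class:`ConfigError` naming it.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config root must be a mapping")

    def block(name: str, keys) -> dict | None:
        if name not in data:
            return None
        blk = data[name]
        if not isinstance(blk, dict):
            raise ConfigError(f"{path}: config block {name!r} must be a mapping")
        for key in keys:
            if key not in blk:
                raise ConfigError(f"{path}: missing config key {name}.{key}")
        return {k: blk[k] for k in keys}

    geom_data = block("geometry", _GEOM_KEYS)
    param_data = block("params", _PARAM_KEYS)

    geometry = ScreenGeometry(**geom_data) if geom_data else DEFAULT_GEOMETRY
    params = AlgorithmParams(**param_data) if param_data else AlgorithmParams()

    param_overrides = {
        k: v for k, v in overrides.items() if k in _PARAM_KEYS and v is not None
    }
    if param_overrides:
        params = AlgorithmParams(**{**asdict(params), **param_overrides})

    image_size = overrides.get("image_size") or data.get("image_size", (1024, 768))
    sigma_deg = overrides.get("sigma_deg") or data.get("sigma_deg", 1.0)
    click_sigma_deg = overrides.get("click_sigma_deg") or data.get("click_sigma_deg", 2.0)
    return RunConfig(geometry, params, image_size, sigma_deg, click_sigma_deg)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_log(out_path, config: RunConfig, inputs=(), seed=None, extra=None) -> Path:
    """Write a JSON sidecar recording parameters, seed, input hashes and
    library versions next to ``out_path``; returns the log path."""
    log = {
        "config": config.to_dict(),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        log.update(extra)
    log_path = Path(str(out_path) + ".runlog.json")
    log_path.write_text(json.dumps(log, indent=2, default=str))
    return log_path
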