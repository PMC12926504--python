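"""File formats and run configuration.

Formats:

* spectra — 2-column CSV ``(wavelength_nm, value)`` with a one-line header
  (see :mod:`fluordepth.optics`);
* images — float32 grayscale TIFF, row-major, image origin at the medium's
  ``(x=0, y=0)`` corner, physical pixel size and run metadata in a JSON
  sidecar next to the file;
* 3D absorption maps — raw float32 binary plus a JSON sidecar recording
  shape, dtype and voxel size;
* configs — YAML, schema-validated before execution (unknown keys are
  rejected with the offending field path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
import yaml

from .mc import AbsorptionMap, SurfaceImage

__all__ = [
    "write_surface_image",
    "read_surface_image",
    "write_absorption_map",
    "read_absorption_map",
    "ConfigError",
    "load_run_config",
    "validate_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(meta: Mapping[str, Any]) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (str, int, float, bool)) or v is None:
            out[k] = v
        elif isinstance(v, (list, tuple)):
            out[k] = list(v)
        else:
            out[k] = repr(v)
    return out


def write_surface_image(path, image: SurfaceImage) -> None:
    """Write a surface image as float32 TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    meta = {
        "pixel_mm": image.pixel_mm,
        "wavelength_nm": image.wavelength_nm,
        **_jsonable(image.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_surface_image(path) -> SurfaceImage:
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return SurfaceImage(
        pixels=pixels,
        pixel_mm=float(meta.get("pixel_mm", 1.0)),
        wavelength_nm=float(meta.get("wavelength_nm", 0.0)),
        metadata=meta,
    )


def write_absorption_map(path, amap: AbsorptionMap) -> None:
    """Write a 3D absorption map as raw float32 plus a JSON sidecar."""
    path = Path(path)
    amap.grid.astype(np.float32).tofile(path)
    _sidecar(path).write_text(
        json.dumps(
            {
                "shape": list(amap.grid.shape),
                "dtype": "float32",
                "order": "C",
                "voxel_mm": amap.voxel_mm,
                "wavelength_nm": amap.wavelength_nm,
                "n_photons": amap.n_photons,
                "seed": amap.seed,
            },
            indent=2,
        )
    )


def read_absorption_map(path) -> np.ndarray:
    """Read back a raw absorption map (array only; sidecar gives geometry)."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.fromfile(path, dtype=meta["dtype"])
    return data.reshape(meta["shape"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


# section -> {key: (required, type)}
_SCHEMA: dict[str, dict[str, tuple[bool, type]]] = {
    "seed": {},
    "medium": {
        "dims_mm": (True, list),
        "voxel_mm": (True, (int, float)),
        "n": (False, (int, float)),
        "g": (False, (int, float)),
        "mua_csv": (False, str),
        "musp_csv": (False, str),
        "preset": (False, str),
    },
    "inclusion": {
        "shape": (True, str),
        "radius_mm": (True, (int, float)),
        "depth_mm": (True, (int, float)),
        "thickness_mm": (False, (int, float)),
        "axis": (False, str),
    },
    "fluorophore": {
        "excitation_csv": (False, str),
        "emission_csv": (False, str),
        "preset": (False, str),
        "concentration_uM": (False, (int, float)),
        "quantum_yield": (False, (int, float)),
        "peak_extinction_cm_M": (False, (int, float)),
    },
    "channels": {
        "approach": (False, str),
        "target_nm": (True, (int, float)),
        "reference_nm": (True, (int, float)),
        "emission_nm": (False, (int, float)),
        "bandwidth_nm": (False, (int, float)),
    },
    "transport": {
        "n_photons": (False, int),
        "emission_photons": (False, int),
        "roulette_threshold": (False, (int, float)),
        "roulette_survival": (False, (int, float)),
        "source": (False, str),
    },
    "model": {
        "geometry": (False, str),
        "source": (False, str),
        "convention": (False, str),
        "intercept_form": (False, str),
    },
    "depths_mm": {},
    "study": {
        "kind": (True, str),
        "depths_mm": (False, list),
        "radii_mm": (False, list),
        "shapes": (False, list),
        "forward": (False, str),
    },
}

_REQUIRED_TOP = ("seed", "medium", "channels")


def validate_config(cfg: Mapping[str, Any], required=_REQUIRED_TOP) -> None:
    """Validate a run config dict; unknown keys anywhere are rejected."""
    if not isinstance(cfg, Mapping):
        raise ConfigError("config must be a mapping")
    for key in required:
        if key not in cfg:
            raise ConfigError(f"missing required field '{key}'")
    for key, value in cfg.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown field '{key}'")
        section = _SCHEMA[key]
        if not section:
            continue  # scalar/list leaves (seed, depths_mm)
        if not isinstance(value, Mapping):
            raise ConfigError(f"field '{key}' must be a mapping")
        for sub, subval in value.items():
            if sub not in section:
                raise ConfigError(f"unknown field '{key}.{sub}'")
            _, typ = section[sub]
            if not isinstance(subval, typ):
                raise ConfigError(
                    f"field '{key}.{sub}' has type {type(subval).__name__}"
                )
        for sub, (req, _) in section.items():
            if req and sub not in value:
                raise ConfigError(f"missing required field '{key}.{sub}'")


@dataclass
class RunConfig:
    """A validated run configuration plus its source path."""

    data: dict
    path: Path | None = None

    def resolved_copy_to(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dest = out / "resolved_config.yaml"
        dest.write_text(yaml.safe_dump(self.data, sort_keys=False))
        return dest


def load_run_config(path, required=_REQUIRED_TOP) -> RunConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    validate_config(data, required)
    return RunConfig(data=data, path=path)
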