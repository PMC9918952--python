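"""Raster and configuration I/O plus run manifests.

Rasters: 8/16-bit integer TIFF/PNG and 32-bit float TIFF, with a JSON
sidecar (``<file>.json``) carrying pitch/wavelength/plane metadata.  Complex
fields are stored as paired float TIFFs (real, imag).  Configuration is a
flat YAML/JSON mapping validated into :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .optics import OpticalGeometry
from .propagation import ComplexField

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_raster",
    "write_raster",
    "write_field",
    "read_field",
    "file_sha256",
]

_DEFAULTS = {
    "k": 1.0,
    "iterations": 2,
    "pad_factor": 2,
    "cfa": "rggb",
    "bit_depth": 12,
    "shot_noise": True,
    "read_sigma": 0.005,
    "gain": 2500.0,
    "crosstalk_leakage": 0.10,
    "seed": 0,
    "equalize_mode": "subtract",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated workflow configuration shared by all CLI stages."""

    geometry: OpticalGeometry
    wavelengths: tuple[float, ...]
    cfa: str = "rggb"
    k: float = 1.0
    iterations: int = 2
    pad_factor: int = 2
    bit_depth: int | None = 12
    shot_noise: bool = True
    read_sigma: float = 0.005
    gain: float = 2500.0
    crosstalk_leakage: float = 0.10
    equalize_mode: str = "subtract"
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ValueError(f"config is missing required field {key!r}")
    return cfg[key]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config file, filling defaults.

    Required keys: ``d``, ``z``, ``pixel_pitch``, ``nx``, ``ny``,
    ``wavelengths`` (list, meters).  All distances in meters.  Violated
    geometry invariants are reported naming the offending field.
    """
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")

    d = float(_require(cfg, "d"))
    z = float(_require(cfg, "z"))
    if z >= d:
        raise ValueError("z must be < d")
    geom = OpticalGeometry(
        d=d,
        z=z,
        pitch=float(_require(cfg, "pixel_pitch")),
        nx=int(_require(cfg, "nx")),
        ny=int(_require(cfg, "ny")),
    )
    wavelengths = tuple(float(w) for w in _require(cfg, "wavelengths"))
    if not wavelengths or any(w <= 0 for w in wavelengths):
        raise ValueError("wavelengths must be a non-empty list of positive values")

    merged = dict(_DEFAULTS)
    known = set(_DEFAULTS) | {"d", "z", "pixel_pitch", "nx", "ny", "wavelengths"}
    extra = {k: v for k, v in cfg.items() if k not in known}
    merged.update({k: v for k, v in cfg.items() if k in _DEFAULTS})
    if merged["iterations"] < 0:
        raise ValueError("iterations must be >= 0")
    return RunConfig(
        geometry=geom,
        wavelengths=wavelengths,
        cfa=str(merged["cfa"]),
        k=float(merged["k"]),
        iterations=int(merged["iterations"]),
        pad_factor=int(merged["pad_factor"]),
        bit_depth=None if merged["bit_depth"] in (None, "none") else int(merged["bit_depth"]),
        shot_noise=bool(merged["shot_noise"]),
        read_sigma=float(merged["read_sigma"]),
        gain=float(merged["gain"]),
        crosstalk_leakage=float(merged["crosstalk_leakage"]),
        equalize_mode=str(merged["equalize_mode"]),
        seed=int(merged["seed"]),
        extra=extra,
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML; ``load_config`` round-trips it."""
    g = config.geometry
    out = {
        "d": g.d,
        "z": g.z,
        "pixel_pitch": g.pitch,
        "nx": g.nx,
        "ny": g.ny,
        "wavelengths": list(config.wavelengths),
        "cfa": config.cfa,
        "k": config.k,
        "iterations": config.iterations,
        "pad_factor": config.pad_factor,
        "bit_depth": config.bit_depth,
        "shot_noise": config.shot_noise,
        "read_sigma": config.read_sigma,
        "gain": config.gain,
        "crosstalk_leakage": config.crosstalk_leakage,
        "equalize_mode": config.equalize_mode,
        "seed": config.seed,
    }
    out.update(config.extra)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Lossless raster write with a JSON metadata sidecar.

    Integer arrays go out as 8/16-bit TIFF or PNG by extension; float arrays
    as 32-bit float TIFF.  Unsupported dtypes raise.
    """
    path = Path(path)
    image = np.asarray(image)
    if image.dtype in (np.uint8, np.uint16):
        data = image
    elif np.issubdtype(image.dtype, np.floating):
        if path.suffix.lower() == ".png":
            raise ValueError("float images must be written as TIFF, not PNG")
        data = image.astype(np.float32)
    else:
        raise ValueError(f"unsupported raster dtype {image.dtype}")
    if path.suffix.lower() in (".tif", ".tiff"):
        if data.ndim == 3:
            tifffile.imwrite(path, data, photometric="minisblack")
        else:
            tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=1))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raster and its sidecar; missing sidecar warns and yields {}."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        image = iio.imread(path)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no metadata sidecar for {path.name}; using defaults", stacklevel=2)
        meta = {}
    return image, meta


def write_field(path_stem: str | Path, f: ComplexField) -> None:
    """Store a complex field as paired float32 TIFFs (real, imag) + sidecar."""
    stem = Path(path_stem)
    meta = {"pitch": f.pitch, "wavelength": f.wavelength, "plane": f.plane}
    write_raster(stem.with_suffix(".real.tif"), np.real(f.values).astype(np.float32), meta)
    write_raster(stem.with_suffix(".imag.tif"), np.imag(f.values).astype(np.float32))


def read_field(path_stem: str | Path) -> ComplexField:
    stem = Path(path_stem)
    re, meta = read_raster(stem.with_suffix(".real.tif"))
    im, _ = read_raster(stem.with_suffix(".imag.tif"))
    return ComplexField(
        re.astype(np.float64) + 1j * im.astype(np.float64),
        pitch=float(meta.get("pitch", 1.0)),
        wavelength=float(meta.get("wavelength", 1.0)),
        plane=str(meta.get("plane", "custom")),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
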