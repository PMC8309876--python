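"""Hologram and table I/O: 16-bit TIFF with JSON sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .optics import Hologram, OpticalConfig

_CONFIG_KEYS = (
    "wavelength_um",
    "pixel_pitch_um",
    "sensor_shape",
    "working_length_mm",
    "exposure_volume_l",
    "pupil_area_mm2",
    "medium_refractive_index",
)


def config_to_dict(config: OpticalConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sensor_shape"] = list(d["sensor_shape"])
    return d


def config_from_dict(d: dict) -> OpticalConfig:
    kwargs = {k: d[k] for k in _CONFIG_KEYS if k in d}
    if "sensor_shape" in kwargs:
        kwargs["sensor_shape"] = tuple(int(v) for v in kwargs["sensor_shape"])
    if "sensor_rows" in d and "sensor_cols" in d:
        kwargs["sensor_shape"] = (int(d["sensor_rows"]), int(d["sensor_cols"]))
    return OpticalConfig(**kwargs)


def read_config(path: str | Path) -> OpticalConfig:
    """Read an optics config from a flat-key JSON file."""
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def write_config(config: OpticalConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)


def write_hologram(hologram: Hologram, path: str | Path, ground_truth: dict | None = None) -> None:
    """Write a hologram as 16-bit grayscale TIFF plus a JSON sidecar.

    Float intensities are quantised to the full 16-bit range; the scale
    factor is stored in the sidecar so reading restores the values.
    """
    path = Path(path)
    I = hologram.intensity
    peak = float(I.max()) if I.max() > 0 else 1.0
    scale = 65535.0 / peak
    data = np.round(I * scale).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "config": config_to_dict(hologram.config),
        "intensity_scale": scale,
        "depth_of_cast_m": hologram.depth_of_cast_m,
        "timestamp_index": hologram.timestamp_index,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_hologram(path: str | Path, config: OpticalConfig | None = None) -> Hologram:
    """Read a hologram from TIFF (or PNG) with its JSON sidecar.

    Without a sidecar the optics config must be supplied explicitly.
    8-bit PNG input is accepted with a precision warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
        if data.ndim == 3:
            data = data[..., 0]
        if data.dtype == np.uint8:
            warnings.warn("8-bit image input: reduced intensity precision", stacklevel=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    scale = 1.0
    depth = None
    ts = 0
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        config = config_from_dict(sidecar["config"])
        scale = float(sidecar.get("intensity_scale", 1.0))
        depth = sidecar.get("depth_of_cast_m")
        ts = int(sidecar.get("timestamp_index", 0))
    elif config is None:
        raise ValueError(f"no sidecar {sidecar_path.name}: an OpticalConfig is required")
    intensity = np.asarray(data, dtype=float) / scale
    return Hologram(intensity, config, depth_of_cast_m=depth, timestamp_index=ts)


def write_mask_stack(scene, path: str | Path) -> None:
    """Export a scene's ground-truth silhouettes as a multi-page TIFF.

    Each page is the full sensor frame with one particle's binary mask
    painted at its (x, y) position (255 = particle).
    """
    from .optics import _place_mask

    cfg = scene.config
    shape = tuple(cfg.sensor_shape)
    pages = [
        (
            _place_mask(q.mask, q.x_um, q.y_um, shape, cfg.pixel_pitch_um) * 255
        ).astype(np.uint8)
        for q in scene.particles
    ]
    if not pages:
        pages = [np.zeros(shape, np.uint8)]
    tifffile.imwrite(Path(path), np.stack(pages), photometric="minisblack")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a particle/profile table as UTF-8 CSV with a stable header."""
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
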