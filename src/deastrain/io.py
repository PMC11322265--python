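"""PNG / JSON / CSV persistence helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image

from .device import DeviceConfig, StrainField

__all__ = [
    "save_gray_png",
    "load_gray_png",
    "save_field",
    "load_field",
    "load_voltage_csv",
    "save_voltage_csv",
]


def save_gray_png(gray01: np.ndarray, path: str | Path, bit_depth: int = 16) -> Path:
    """Write a [0, 1] grayscale array as an 8- or 16-bit PNG."""
    arr = np.clip(np.asarray(gray01, dtype=float), 0.0, 1.0)
    path = Path(path)
    if bit_depth == 8:
        img = Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L")
    elif bit_depth == 16:
        img = Image.fromarray(np.round(arr * 65535).astype(np.uint16), mode="I;16")
    else:
        raise ValueError("bit_depth must be 8 or 16")
    img.save(path)
    return path


def load_gray_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back to a [0, 1] float array."""
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=float)
    scale = 255.0 if arr.max() <= 255 else 65535.0
    return arr / scale


def save_field(
    field: StrainField, config: DeviceConfig, path: str | Path
) -> Tuple[Path, Path]:
    """Persist a strain field as PNG + JSON sidecar recording units and range."""
    path = Path(path)
    png_path = path if path.suffix == ".png" else path.with_suffix(".png")
    save_gray_png(field.to_gray(config), png_path)
    sidecar = png_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "axis": field.axis,
                "size": field.size,
                "strain_display_min": config.strain_display_min,
                "strain_display_max": config.strain_display_max,
                "units": "calibration-curve strain scale",
            },
            indent=2,
        )
    )
    return png_path, sidecar


def load_field(path: str | Path, config: DeviceConfig) -> StrainField:
    png_path = Path(path)
    gray = load_gray_png(png_path)
    sidecar = png_path.with_suffix(".json")
    axis = "X"
    if sidecar.exists():
        axis = json.loads(sidecar.read_text()).get("axis", "X")
    return StrainField(axis, config.display_denormalize(gray))


def save_voltage_csv(voltages: np.ndarray, path: str | Path, grid_n: int = 9) -> Path:
    arr = np.asarray(voltages, dtype=float).reshape(-1, grid_n * grid_n)
    header = ",".join(f"v{r}{c}" for r in range(grid_n) for c in range(grid_n))
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")
    return Path(path)


def load_voltage_csv(path: str | Path, grid_n: int = 9) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return arr.reshape(-1, grid_n, grid_n)
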