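"""Virtual dielectric-elastomer-actuator (DEA) array device.

This module holds the calibration curve of a single actuator pixel
(voltage -> strain, a dual-Gaussian fit), strain conversions, and a
closed-form surrogate simulator that maps a 9x9 voltage array to the
X- and Y-direction strain fields the device would produce.

The surrogate is deliberately simple but keeps the three properties the
learning pipeline depends on:

* a nonlinear, strictly monotone per-pixel voltage -> strain response;
* anisotropic rendering: each strain axis varies smoothly along its own
  direction (piecewise-linear interpolation through pixel-centre values)
  but holds near-plateaus across it, so cross-axis gradients come out as
  staircases — the device's directional limitation;
* a clamped boundary frame: strain tapers to the undeformed value over a
  configurable margin.

Pixel centres are fixed points of the rendering (up to a small coupling
blur across the strain axis), so the marginal distribution of commanded
strains survives simulation — the property the uniform-strain sampling
scheme relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "DeviceConfig",
    "VoltageStrainCurve",
    "VoltageArray",
    "StrainField",
    "engineering_to_true_strain",
    "strain_from_voltage",
    "voltage_from_strain",
    "reachable_strain_range",
    "simulate",
    "render_strain_field",
    "downsample_field",
]


@dataclass(frozen=True)
class DeviceConfig:
    """Geometry, actuation range and rendering parameters of the virtual device.

    ``coupling_sigma_parallel`` / ``coupling_sigma_perpendicular`` are the
    Gaussian coupling scales in units of one pixel footprint, applied along /
    across the strain axis of each rendered field.  ``boundary_margin`` is the
    fraction of the field width over which strain ramps down to the clamped,
    undeformed frame.
    """

    grid_n: int = 9
    membrane_side: float = 100.0          # mm
    prestretch_engineering: float = 1.0   # 100% biaxial engineering strain
    voltage_min: float = 0.0              # kV
    voltage_max: float = 7.1              # kV
    coupling_sigma_parallel: float = 0.0  # pixel footprints, along strain axis
    coupling_sigma_perpendicular: float = 0.10  # pixel footprints, across
    boundary_margin: float = 1.0 / 30.0   # fraction of field width
    hr_size: int = 480
    lr_size: int = 60
    strain_display_min: float = 0.0
    strain_display_max: float = 70.0
    frame_strain: float = 0.0             # strain of the clamped frame

    def __post_init__(self) -> None:
        if self.grid_n < 1:
            raise ValueError("grid_n must be >= 1")
        if not self.voltage_min < self.voltage_max:
            raise ValueError("voltage_min must be < voltage_max")
        if not 0.0 <= self.boundary_margin < 0.5:
            raise ValueError("boundary_margin must be in [0, 0.5)")
        if self.hr_size % self.lr_size != 0:
            raise ValueError("hr_size must be an integer multiple of lr_size")
        if self.strain_display_min >= self.strain_display_max:
            raise ValueError("degenerate strain display range")

    @property
    def n_pixels(self) -> int:
        return self.grid_n * self.grid_n

    @property
    def scale_factor(self) -> int:
        return self.hr_size // self.lr_size

    def display_normalize(self, values: np.ndarray) -> np.ndarray:
        """Map strain values linearly onto [0, 1] grayscale."""
        lo, hi = self.strain_display_min, self.strain_display_max
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def display_denormalize(self, gray: np.ndarray) -> np.ndarray:
        lo, hi = self.strain_display_min, self.strain_display_max
        return lo + np.asarray(gray, dtype=float) * (hi - lo)


@dataclass(frozen=True)
class VoltageStrainCurve:
    """Dual-Gaussian single-pixel calibration: strain(V) = a1*exp(-((V-b1)/c1)^2) + a2*exp(-((V-b2)/c2)^2).

    Both Gaussian centres sit above the operating voltage range, so the
    curve is strictly increasing on it.
    """

    a1: float = 7.756e15
    b1: float = 24.1
    c1: float = 2.964
    a2: float = 47.69
    b2: float = 10.18
    c2: float = 4.401

    def __call__(self, voltage: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(voltage, dtype=float)
        out = self.a1 * np.exp(-(((v - self.b1) / self.c1) ** 2)) + self.a2 * np.exp(
            -(((v - self.b2) / self.c2) ** 2)
        )
        return out if out.ndim else float(out)

    def derivative(self, voltage: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(voltage, dtype=float)
        t1 = self.a1 * np.exp(-(((v - self.b1) / self.c1) ** 2)) * (
            2.0 * (self.b1 - v) / self.c1**2
        )
        t2 = self.a2 * np.exp(-(((v - self.b2) / self.c2) ** 2)) * (
            2.0 * (self.b2 - v) / self.c2**2
        )
        out = t1 + t2
        return out if out.ndim else float(out)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("a1", "b1", "c1", "a2", "b2", "c2")}


@dataclass(frozen=True)
class VoltageArray:
    """A grid_n x grid_n matrix of per-pixel voltages in kV."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("voltage array must be a square matrix")
        object.__setattr__(self, "values", vals)

    def validate(self, config: DeviceConfig) -> "VoltageArray":
        if self.values.shape != (config.grid_n, config.grid_n):
            raise ValueError(
                f"expected shape {(config.grid_n, config.grid_n)}, got {self.values.shape}"
            )
        if np.any(self.values < config.voltage_min) or np.any(
            self.values > config.voltage_max
        ):
            raise ValueError(
                f"voltages outside [{config.voltage_min}, {config.voltage_max}] kV"
            )
        return self

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass(frozen=True)
class StrainField:
    """One axis of the simulated strain map (X == LE11, Y == LE22)."""

    axis: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("X", "Y"):
            raise ValueError("axis must be 'X' or 'Y'")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("strain field must be a square 2-D map")
        if not np.all(np.isfinite(vals)):
            raise ValueError("strain field contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def to_gray(self, config: DeviceConfig) -> np.ndarray:
        """Grayscale rendering on [0, 1] using the config display range."""
        return config.display_normalize(self.values)


def engineering_to_true_strain(e: np.ndarray | float) -> np.ndarray | float:
    """Convert engineering strain to true (logarithmic) strain, ln(1 + e)."""
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= -1.0):
        raise ValueError("engineering strain must be > -1")
    out = np.log1p(e_arr)
    return out if out.ndim else float(out)


def strain_from_voltage(
    voltage: np.ndarray | float,
    curve: VoltageStrainCurve | None = None,
    config: DeviceConfig | None = None,
) -> np.ndarray | float:
    """Evaluate the calibration curve, rejecting voltages outside the operating range."""
    curve = curve or VoltageStrainCurve()
    config = config or DeviceConfig()
    v = np.asarray(voltage, dtype=float)
    if np.any(v < config.voltage_min - 1e-12) or np.any(v > config.voltage_max + 1e-12):
        raise ValueError(
            f"voltage outside operating range [{config.voltage_min}, {config.voltage_max}] kV"
        )
    return curve(voltage)


def reachable_strain_range(
    curve: VoltageStrainCurve | None = None, config: DeviceConfig | None = None
) -> Tuple[float, float]:
    """Strain interval reachable on the operating voltage range (curve is monotone)."""
    curve = curve or VoltageStrainCurve()
    config = config or DeviceConfig()
    return float(curve(config.voltage_min)), float(curve(config.voltage_max))


def voltage_from_strain(
    strain: np.ndarray | float,
    curve: VoltageStrainCurve | None = None,
    config: DeviceConfig | None = None,
    tol: float = 1e-9,
) -> np.ndarray | float:
    """Invert the calibration curve on the operating range.

    Uses a dense monotone lookup for bracketing followed by safeguarded
    Newton polishing; accurate to well below ``tol`` kV.
    """
    curve = curve or VoltageStrainCurve()
    config = config or DeviceConfig()
    eps = np.asarray(strain, dtype=float)
    lo, hi = reachable_strain_range(curve, config)
    if np.any(eps < lo - 1e-9) or np.any(eps > hi + 1e-9):
        raise ValueError(
            f"strain outside reachable range [{lo:.6g}, {hi:.6g}] "
            f"(voltages {config.voltage_min}-{config.voltage_max} kV)"
        )
    v_grid, s_grid = _inverse_lookup_table(curve, config.voltage_min, config.voltage_max)
    v = np.interp(np.clip(eps, lo, hi), s_grid, v_grid)
    # Newton polish; the curve is strictly increasing with bounded derivative.
    for _ in range(4):
        f = np.asarray(curve(v)) - np.clip(eps, lo, hi)
        df = np.asarray(curve.derivative(v))
        v = np.clip(v - f / df, config.voltage_min, config.voltage_max)
        if np.max(np.abs(f)) < tol * np.max(np.abs(df)):
            break
    return v if v.ndim else float(v)


@lru_cache(maxsize=8)
def _inverse_lookup_table(curve: VoltageStrainCurve, vmin: float, vmax: float):
    v_grid = np.linspace(vmin, vmax, 4097)
    s_grid = np.asarray(curve(v_grid))
    return v_grid, s_grid


# ---------------------------------------------------------------------------
# Rendering operators
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _interp_matrix(size: int, grid_n: int) -> np.ndarray:
    """size x grid_n tent-basis matrix: piecewise-linear interpolation through
    pixel-centre values, edge-held beyond the outermost centres."""
    centers = (np.arange(grid_n) + 0.5) / grid_n
    u = (np.arange(size) + 0.5) / size
    mat = np.zeros((size, grid_n))
    for j in range(grid_n):
        basis = np.zeros(grid_n)
        basis[j] = 1.0
        mat[:, j] = np.interp(u, centers, basis)
    return mat


@lru_cache(maxsize=32)
def _plateau_matrix(size: int, grid_n: int) -> np.ndarray:
    """size x grid_n matrix assigning each image row to pixel footprints by
    exact area overlap (footprint boundaries fall between image rows when
    size/grid_n is not an integer, so boundary rows get fractional weights).
    Rows are non-negative and sum to 1."""
    mat = np.zeros((size, grid_n))
    for p in range(size):
        lo, hi = p / size, (p + 1) / size
        for j in range(grid_n):
            f_lo, f_hi = j / grid_n, (j + 1) / grid_n
            overlap = max(0.0, min(hi, f_hi) - max(lo, f_lo))
            mat[p, j] = overlap * size
    return mat


@lru_cache(maxsize=32)
def _taper_profile(size: int, margin: float) -> np.ndarray:
    """1-D taper ramping linearly from the clamped frame to 1 over the margin."""
    if margin <= 0.0:
        return np.ones(size)
    u = (np.arange(size) + 0.5) / size
    return np.clip(np.minimum(u, 1.0 - u) / margin, 0.0, 1.0)


def _axis_operators(size: int, config: DeviceConfig):
    interp = _interp_matrix(size, config.grid_n)
    plateau = _plateau_matrix(size, config.grid_n)
    taper = _taper_profile(size, config.boundary_margin)
    return interp, plateau, taper


def _render_x(commanded: np.ndarray, size: int, config: DeviceConfig) -> np.ndarray:
    """Render the X-direction strain map of one or more commanded 9x9 grids.

    ``commanded`` has shape (..., grid_n, grid_n); output (..., size, size).
    Rows (axis -2) index y, columns (axis -1) index x.  Variation along x is
    interpolated through centre values; variation along y is plateau-held and
    blurred by the cross-axis coupling scale.
    """
    interp, plateau, taper = _axis_operators(size, config)
    footprint_px = size / config.grid_n
    # plateau along y (rows), interpolation along x (columns)
    fld = np.einsum("pi,...ij,qj->...pq", plateau, commanded, interp)
    sig_perp = config.coupling_sigma_perpendicular * footprint_px
    if sig_perp > 0:
        fld = ndimage.gaussian_filter1d(fld, sig_perp, axis=-2, mode="nearest")
    sig_par = config.coupling_sigma_parallel * footprint_px
    if sig_par > 0:
        fld = ndimage.gaussian_filter1d(fld, sig_par, axis=-1, mode="nearest")
    frame = config.frame_strain
    mask = np.outer(taper, taper)
    return frame + (fld - frame) * mask


def render_strain_field(
    commanded: np.ndarray, axis: str, size: int, config: DeviceConfig
) -> np.ndarray:
    """Render one strain axis from a commanded per-pixel strain grid."""
    commanded = np.asarray(commanded, dtype=float)
    if axis == "X":
        return _render_x(commanded, size, config)
    if axis == "Y":
        swapped = np.swapaxes(commanded, -1, -2)
        return np.swapaxes(_render_x(swapped, size, config), -1, -2)
    raise ValueError("axis must be 'X' or 'Y'")


def simulate(
    voltages: VoltageArray,
    config: DeviceConfig | None = None,
    curve: VoltageStrainCurve | None = None,
    resolution: str = "hr",
) -> Tuple[StrainField, StrainField]:
    """Surrogate simulation: voltage array -> (X strain field, Y strain field).

    ``resolution`` selects the render size: "hr" (config.hr_size) or
    "lr" (config.lr_size).  Deterministic given its inputs.
    """
    config = config or DeviceConfig()
    curve = curve or VoltageStrainCurve()
    voltages.validate(config)
    size = {"hr": config.hr_size, "lr": config.lr_size}[resolution]
    commanded = np.asarray(curve(voltages.values))
    fx = render_strain_field(commanded, "X", size, config)
    fy = render_strain_field(commanded, "Y", size, config)
    return StrainField("X", fx), StrainField("Y", fy)


def downsample_field(field: StrainField, factor: int) -> StrainField:
    """Area (block-mean) downsampling by an integer factor."""
    size = field.size
    if size % factor != 0:
        raise ValueError("field size must be divisible by the downsampling factor")
    small = field.values.reshape(size // factor, factor, size // factor, factor).mean(
        axis=(1, 3)
    )
    return StrainField(field.axis, small)


def extract_center_strains(field: StrainField, config: DeviceConfig) -> np.ndarray:
    """Sample the field at each pixel footprint's centre point, row-major 81-vector."""
    size = field.size
    if size < config.grid_n:
        raise ValueError("field is coarser than the actuator grid")
    centers = (np.arange(config.grid_n) + 0.5) / config.grid_n * size - 0.5
    rr, cc = np.meshgrid(centers, centers, indexing="ij")
    vals = ndimage.map_coordinates(
        field.values, np.stack([rr.ravel(), cc.ravel()]), order=1, mode="nearest"
    )
    return vals
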