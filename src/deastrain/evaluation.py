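"""Structural-similarity scoring with local maps, and voltage error grids.

SSIM is computed with a sliding Gaussian window: within every window the
weighted mean luminance, variance and covariance of the two images feed
the luminance/contrast/structure comparison functions, whose product (with
C3 = C2/2) collapses to the familiar two-term expression.  Both code paths
are implemented and must agree to numerical precision.  The local map is
evaluated on valid windows only — no padding — and the scalar score is its
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["SSIMParams", "SSIMReport", "local_ssim_map", "mean_ssim", "error_grid"]


@dataclass(frozen=True)
class SSIMParams:
    window_size: int = 11
    gaussian_sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size % 2 != 1 or self.window_size < 3:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0

    def window(self) -> np.ndarray:
        """Normalized 1-D Gaussian window (applied separably)."""
        half = self.window_size // 2
        t = np.arange(-half, half + 1, dtype=float)
        w = np.exp(-(t**2) / (2.0 * self.gaussian_sigma**2))
        return w / w.sum()


@dataclass(frozen=True)
class SSIMReport:
    mean_ssim: float
    local_map: np.ndarray
    params: SSIMParams


def _windowed(img: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Separable weighted local mean over valid windows only."""
    half = len(w) // 2
    out = ndimage.correlate1d(img, w, axis=0, mode="constant")
    out = ndimage.correlate1d(out, w, axis=1, mode="constant")
    return out[half:-half, half:-half]


def local_ssim_map(
    x: np.ndarray,
    y: np.ndarray,
    params: SSIMParams | None = None,
    three_term: bool = False,
) -> np.ndarray:
    """Local SSIM map of two single-channel images over valid windows.

    ``three_term=True`` computes the explicit luminance x contrast x
    structure product (with C3 = C2/2); the default uses the reduced
    two-term form.  The two agree to floating-point precision.
    """
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("images must be 2-D arrays of identical shape")
    if min(x.shape) < params.window_size:
        raise ValueError("images smaller than the SSIM window")
    w = params.window()
    mu_x = _windowed(x, w)
    mu_y = _windowed(y, w)
    mu_xx = _windowed(x * x, w)
    mu_yy = _windowed(y * y, w)
    mu_xy = _windowed(x * y, w)
    var_x = mu_xx - mu_x**2
    var_y = mu_yy - mu_y**2
    cov = mu_xy - mu_x * mu_y

    c1, c2, c3 = params.c1, params.c2, params.c3
    lum = (2.0 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    if three_term:
        sx = np.sqrt(np.maximum(var_x, 0.0))
        sy = np.sqrt(np.maximum(var_y, 0.0))
        contrast = (2.0 * sx * sy + c2) / (var_x + var_y + c2)
        structure = (cov + c3) / (sx * sy + c3)
        return lum * contrast * structure
    cs = (2.0 * cov + c2) / (var_x + var_y + c2)
    return lum * cs


def mean_ssim(
    x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None
) -> SSIMReport:
    """Mean of the local SSIM map, bundled with the map itself."""
    params = params or SSIMParams()
    local = local_ssim_map(x, y, params)
    return SSIMReport(mean_ssim=float(local.mean()), local_map=local, params=params)


def error_grid(
    predicted: Sequence[np.ndarray], truth: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-pixel mean absolute voltage error across aligned prediction/truth lists."""
    if len(predicted) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    if len(predicted) == 0:
        raise ValueError("empty lists")

    def _vals(a):
        return a.values if hasattr(a, "values") else np.asarray(a, dtype=float)

    pred = np.stack([_vals(p) for p in predicted])
    true = np.stack([_vals(t) for t in truth])
    if pred.shape != true.shape:
        raise ValueError("prediction and truth shapes differ")
    return np.abs(pred - true).mean(axis=0)
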