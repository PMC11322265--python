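"""Demonstration targets and the reproduce-and-score workflow.

Targets are rendered in the active-region image space used throughout the
pipeline: a square grayscale map on [0, 1] whose intensity scale is the
device display range.  Three families are provided:

* ``annuli`` — concentric rings of distinct strain levels (vessel-like
  circular tissue structures);
* ``gradient`` — a unidirectional linear strain ramp (tendon/muscle-like
  graded loading);
* ``interface`` — a smooth random blob (a Fourier-perturbed ellipse)
  separating an inside strain level from an outside one, emulating a
  tumor–stroma interface shape.

``reproduce`` closes the loop: target image -> inverse model -> voltages
-> surrogate simulation -> SSIM score against the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .device import (
    DeviceConfig,
    StrainField,
    VoltageArray,
    VoltageStrainCurve,
    reachable_strain_range,
    simulate,
)
from .evaluation import SSIMParams, SSIMReport, mean_ssim
from .inverse import InverseModel, predict_voltages, preprocess_field

__all__ = ["TargetSpec", "make_target", "reproduce", "default_annuli_spec", "default_gradient_spec"]

_CANONICAL_INTERFACE_SEEDS = (11, 23, 47)  # three shipped tumor-interface shapes


@dataclass(frozen=True)
class TargetSpec:
    """Parametric description of a demonstration target image.

    ``params`` by kind:

    * annuli: ``rings`` = sequence of (outer_radius_fraction, level) with
      increasing radii, ``background`` level; levels are strain display
      units (e.g. 0-70).
    * gradient: ``direction`` in {"horizontal", "vertical"}, ``lo``, ``hi``
      strain levels at the two ends.
    * interface: ``seed``, ``inside``, ``outside`` levels, optional
      ``n_modes``, ``roughness``, ``radius``, ``aspect``.
    """

    kind: str
    params: dict = field(default_factory=dict)
    size: int = 60

    def __post_init__(self) -> None:
        if self.kind not in ("annuli", "gradient", "interface"):
            raise ValueError("kind must be annuli, gradient or interface")
        if self.size < 8:
            raise ValueError("render size too small")


def default_gradient_spec(
    direction: str = "horizontal",
    config: DeviceConfig | None = None,
    curve: VoltageStrainCurve | None = None,
    size: int = 60,
) -> TargetSpec:
    """Linear ramp spanning the reachable strain range."""
    lo, hi = reachable_strain_range(curve, config)
    return TargetSpec("gradient", {"direction": direction, "lo": lo, "hi": hi}, size)


def default_annuli_spec(size: int = 60) -> TargetSpec:
    """Three concentric rings at display levels 25 / 45 / 65.

    Ring transitions are softened to about half a pixel footprint: the
    9 x 9 device cannot render sharp sub-footprint edges, and the
    demonstration targets are meant to be device-plausible.
    """
    return TargetSpec(
        "annuli",
        {
            "rings": [(0.18, 65.0), (0.33, 45.0), (0.48, 25.0)],
            "background": 5.0,
            "soften_sigma": 3.0,
        },
        size,
    )


def _level01(level: float, config: DeviceConfig) -> float:
    return float(config.display_normalize(np.asarray(level)))


def make_target(spec: TargetSpec, config: DeviceConfig | None = None) -> np.ndarray:
    """Render a target grayscale image on [0, 1]; deterministic per spec."""
    config = config or DeviceConfig()
    s = spec.size
    u = (np.arange(s) + 0.5) / s
    if spec.kind == "gradient":
        lo = _level01(spec.params["lo"], config)
        hi = _level01(spec.params["hi"], config)
        ramp = lo + (hi - lo) * u
        if spec.params.get("direction", "horizontal") == "horizontal":
            return np.tile(ramp, (s, 1))
        return np.tile(ramp[:, None], (1, s))

    yy, xx = np.meshgrid(u - 0.5, u - 0.5, indexing="ij")
    if spec.kind == "annuli":
        rings: Sequence[Tuple[float, float]] = spec.params["rings"]
        radii = [r for r, _ in rings]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("ring radii must be strictly increasing")
        rr = np.hypot(xx, yy)
        img = np.full((s, s), _level01(spec.params.get("background", 0.0), config))
        inner = 0.0
        for outer, level in rings:
            img[(rr >= inner) & (rr < outer)] = _level01(level, config)
            inner = outer
        soften = float(spec.params.get("soften_sigma", 0.0))
        if soften > 0:
            img = ndimage.gaussian_filter(img, soften, mode="nearest")
        return img

    # interface: Fourier-perturbed ellipse
    p = spec.params
    rng = np.random.default_rng(p.get("seed", _CANONICAL_INTERFACE_SEEDS[0]))
    n_modes = int(p.get("n_modes", 5))
    roughness = float(p.get("roughness", 0.12))
    r0 = float(p.get("radius", 0.3))
    aspect = float(p.get("aspect", 1.3))
    theta = np.arctan2(yy, xx)
    radius = np.hypot(xx * aspect, yy / aspect)
    boundary = np.full_like(theta, r0)
    for k in range(2, 2 + n_modes):
        amp = roughness * r0 * rng.uniform(0.2, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        boundary = boundary + amp * np.cos(k * theta + phase)
    if np.any(boundary <= 0):
        raise ValueError("interface boundary self-intersects; lower roughness")
    inside = _level01(p.get("inside", 60.0), config)
    outside = _level01(p.get("outside", 10.0), config)
    img = np.where(radius <= boundary, inside, outside)
    soften = float(p.get("soften_sigma", 3.0))
    if soften > 0:
        img = ndimage.gaussian_filter(img, soften, mode="nearest")
    return img


def reproduce(
    target: np.ndarray,
    inverse_model: InverseModel,
    config: DeviceConfig | None = None,
    curve: VoltageStrainCurve | None = None,
    axis: Optional[str] = None,
    ssim_params: SSIMParams | None = None,
) -> Tuple[VoltageArray, StrainField, SSIMReport]:
    """Reproduce a target image on the virtual device and score the result.

    Predicts a voltage array from the target with the inverse model,
    simulates it with the surrogate, and computes SSIM between the target
    and the reproduced field (both in active-region grayscale space).
    """
    config = config or inverse_model.config
    curve = curve or VoltageStrainCurve()
    axis = axis or inverse_model.axis
    if axis != inverse_model.axis:
        raise ValueError(
            f"requested axis {axis!r} but inverse model is for {inverse_model.axis!r}"
        )
    volts = predict_voltages(inverse_model, target)
    fields = simulate(volts, config, curve, resolution="lr")
    fld = fields[0] if axis == "X" else fields[1]
    reproduced_img = preprocess_field(fld, config).reshape(
        config.lr_size, config.lr_size
    )
    tgt = np.asarray(target, dtype=float)
    if tgt.shape != reproduced_img.shape:
        raise ValueError("target must be rendered at lr_size for scoring")
    report = mean_ssim(tgt, reproduced_img, ssim_params)
    return volts, fld, report
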