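"""Voltage-array sampling, calibration fitting, dataset construction and
strain-distribution uniformity metrics.

Two sampling schemes are provided: the naive ``uniform_voltage`` baseline
(i.i.d. uniform voltages, which the nonlinear calibration turns into a
badly skewed strain distribution) and ``uniform_strain``, which draws
per-pixel strains uniformly over the reachable range and inverts the
calibration curve — the redistribution that makes the training set cover
every strain level evenly.
"""

from __future__ import annotations

import hashlib
import math
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .device import (
    DeviceConfig,
    StrainField,
    VoltageArray,
    VoltageStrainCurve,
    extract_center_strains,
    reachable_strain_range,
    render_strain_field,
    voltage_from_strain,
)

__all__ = [
    "SamplingScheme",
    "Dataset",
    "sample_voltage_arrays",
    "extract_center_strains",
    "strain_distribution_metrics",
    "fit_dual_gaussian",
    "build_dataset",
]


@dataclass(frozen=True)
class SamplingScheme:
    """How to draw 81-D voltage arrays.

    ``strain_lo``/``strain_hi`` bound the sampled strains for the
    ``uniform_strain`` scheme; they default to the reachable range of the
    calibration curve.
    """

    kind: str = "uniform_strain"
    seed: int = 0
    strain_lo: Optional[float] = None
    strain_hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_voltage", "uniform_strain"):
            raise ValueError("kind must be 'uniform_voltage' or 'uniform_strain'")

    def strain_bounds(
        self, curve: VoltageStrainCurve, config: DeviceConfig
    ) -> Tuple[float, float]:
        lo_r, hi_r = reachable_strain_range(curve, config)
        lo = lo_r if self.strain_lo is None else self.strain_lo
        hi = hi_r if self.strain_hi is None else self.strain_hi
        if not lo < hi:
            raise ValueError("strain_lo must be < strain_hi")
        if lo < lo_r - 1e-9 or hi > hi_r + 1e-9:
            raise ValueError(
                f"strain bounds [{lo}, {hi}] outside reachable range [{lo_r:.4g}, {hi_r:.4g}]"
            )
        return lo, hi


def sample_voltage_arrays(
    n: int,
    scheme: SamplingScheme,
    curve: VoltageStrainCurve | None = None,
    config: DeviceConfig | None = None,
) -> List[VoltageArray]:
    """Draw ``n`` seeded voltage arrays under the given scheme."""
    if n < 1:
        raise ValueError("n must be >= 1")
    curve = curve or VoltageStrainCurve()
    config = config or DeviceConfig()
    rng = np.random.default_rng(scheme.seed)
    g = config.grid_n
    if scheme.kind == "uniform_voltage":
        volts = rng.uniform(config.voltage_min, config.voltage_max, size=(n, g, g))
    else:
        lo, hi = scheme.strain_bounds(curve, config)
        eps = rng.uniform(lo, hi, size=(n, g, g))
        volts = np.asarray(voltage_from_strain(eps, curve, config))
    return [VoltageArray(v) for v in volts]


def strain_distribution_metrics(
    strains: Sequence[float] | np.ndarray,
    n_bins: int = 7,
    strain_lo: Optional[float] = None,
    strain_hi: Optional[float] = None,
) -> Tuple[float, float]:
    """Uniformity metrics of a pooled strain sample.

    Histograms the values into ``n_bins`` equal-width bins on
    [strain_lo, strain_hi] (defaults to the sample range) and returns

    * the sample standard deviation of the bin probabilities, and
    * the Shannon entropy -sum p_k ln p_k (natural log, 0*ln 0 = 0).

    A perfectly uniform occupancy gives (0, ln n_bins).
    """
    vals = np.asarray(strains, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 strain values")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    lo = float(np.min(vals)) if strain_lo is None else float(strain_lo)
    hi = float(np.max(vals)) if strain_hi is None else float(strain_hi)
    if hi <= lo:
        warnings.warn("degenerate strain range; all mass in a single bin")
        probs = np.zeros(n_bins)
        probs[0] = 1.0
    else:
        counts, _ = np.histogram(vals, bins=n_bins, range=(lo, hi))
        probs = counts / counts.sum()
    std_p = float(np.std(probs, ddof=1))
    nz = probs[probs > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    return std_p, entropy


def _dual_gaussian_logamp(v, la1, b1, c1, la2, b2, c2):
    # log-amplitude parametrization: the two Gaussian amplitudes can differ
    # by 14 orders of magnitude (peaks far above the operating range), which
    # the raw-amplitude least-squares problem cannot navigate
    return np.exp(la1 - (((v - b1) / c1) ** 2)) + np.exp(la2 - (((v - b2) / c2) ** 2))


def fit_dual_gaussian(
    v_samples: np.ndarray,
    eps_samples: np.ndarray,
    maxfev: int = 40000,
    n_restarts: int = 6,
) -> Tuple[VoltageStrainCurve, float]:
    """Nonlinear least-squares fit of the six dual-Gaussian parameters.

    Fits in a log-amplitude parametrization from a handful of neutral
    seeded initializations (two positive Gaussians centred above the
    sampled voltage range, amplitude scales taken from the data) and keeps
    the best.  Returns the fitted curve and the coefficient of
    determination on the fitting data.
    """
    v = np.asarray(v_samples, dtype=float).ravel()
    eps = np.asarray(eps_samples, dtype=float).ravel()
    if v.size != eps.size:
        raise ValueError("voltage and strain sample lengths differ")
    if v.size < 6:
        raise ValueError("need at least 6 samples to fit 6 parameters")
    if np.ptp(eps) == 0:
        warnings.warn("constant strain data; dual-Gaussian fit is undefined")
        return VoltageStrainCurve(0, 1, 1, float(eps[0]), 1e6, 1e6), float("nan")

    vmax = float(np.max(v))
    log_emax = math.log(max(float(np.max(np.abs(eps))), 1e-12))
    bounds = (
        [-30.0, vmax, 1e-2, -30.0, vmax, 1e-2],
        [80.0, 30.0 * vmax, 30.0 * vmax, 80.0, 30.0 * vmax, 30.0 * vmax],
    )
    rng = np.random.default_rng(0)
    best: Tuple[float, np.ndarray] | None = None
    last_err: Exception | None = None
    for trial in range(n_restarts):
        jitter = rng.uniform(0.8, 1.25, 4) if trial else np.ones(4)
        p0 = [
            log_emax * jitter[0],
            1.6 * vmax * jitter[1],
            0.5 * vmax * jitter[2],
            log_emax,
            2.2 * vmax * jitter[3],
            0.9 * vmax,
        ]
        try:
            popt, _ = curve_fit(
                _dual_gaussian_logamp, v, eps, p0=p0, bounds=bounds, maxfev=maxfev
            )
        except RuntimeError as err:  # pragma: no cover - optimizer dependent
            last_err = err
            continue
        ss_res = float(np.sum((eps - _dual_gaussian_logamp(v, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:  # pragma: no cover - all restarts failed
        raise RuntimeError(f"dual-Gaussian fit did not converge: {last_err}")
    ss_res, popt = best
    ss_tot = float(np.sum((eps - eps.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    curve = VoltageStrainCurve(
        math.exp(popt[0]), popt[1], popt[2], math.exp(popt[3]), popt[4], popt[5]
    )
    return curve, r2


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """In-memory surrogate dataset: voltage arrays plus rendered strain fields.

    ``lr_x``/``lr_y`` hold low-resolution strain maps (strain units) for
    every sample; high-resolution maps are rendered on demand to keep the
    memory footprint flat at the 10,000-sample scale.
    """

    voltages: np.ndarray          # (n, grid_n, grid_n) kV
    lr_x: np.ndarray              # (n, lr, lr) float32, strain units
    lr_y: np.ndarray              # (n, lr, lr) float32, strain units
    split: np.ndarray             # (n,) array of "train"/"test"
    config: DeviceConfig
    curve: VoltageStrainCurve
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.voltages.shape[0]

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def subset_voltages(self, split: str) -> np.ndarray:
        return self.voltages[self.indices(split)]

    def lr_fields(self, axis: str, split: Optional[str] = None) -> np.ndarray:
        arr = {"X": self.lr_x, "Y": self.lr_y}[axis]
        return arr if split is None else arr[self.indices(split)]

    def hr_field(self, index: int, axis: str) -> StrainField:
        commanded = np.asarray(self.curve(self.voltages[index]))
        vals = render_strain_field(commanded, axis, self.config.hr_size, self.config)
        return StrainField(axis, vals)

    def manifest(self) -> dict:
        h = hashlib.sha256()
        for arr in (self.voltages, self.lr_x, self.lr_y):
            h.update(np.ascontiguousarray(arr, dtype=np.float32).tobytes())
        return {
            "n_train": int(np.sum(self.split == "train")),
            "n_test": int(np.sum(self.split == "test")),
            "grid_n": self.config.grid_n,
            "lr_size": self.config.lr_size,
            "hr_size": self.config.hr_size,
            "curve": self.curve.as_dict(),
            "content_sha256": h.hexdigest(),
            **self.provenance,
        }

    def save(self, out_dir: str | Path, store_hr: bool = False) -> Path:
        """Write the dataset as PNG images + a voltages CSV + manifest.json."""
        from .io import save_gray_png

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for i in range(self.n):
            for axis, arr in (("x", self.lr_x[i]), ("y", self.lr_y[i])):
                gray = self.config.display_normalize(arr)
                save_gray_png(gray, img_dir / f"sample{i:05d}_lr_{axis}.png")
            if store_hr:
                for axis in ("X", "Y"):
                    gray = self.hr_field(i, axis).to_gray(self.config)
                    save_gray_png(
                        gray, img_dir / f"sample{i:05d}_hr_{axis.lower()}.png"
                    )
        header = ",".join(
            f"v{r}{c}" for r in range(self.config.grid_n) for c in range(self.config.grid_n)
        )
        np.savetxt(
            out / "voltages.csv",
            self.voltages.reshape(self.n, -1),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.6f",
        )
        (out / "split.csv").write_text("\n".join(self.split) + "\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))
        return out


def build_dataset(
    n_train: int,
    n_test: int,
    scheme: SamplingScheme | None = None,
    config: DeviceConfig | None = None,
    curve: VoltageStrainCurve | None = None,
    out_dir: Optional[str | Path] = None,
    store_hr: bool = False,
) -> Dataset:
    """Sample voltage arrays, simulate every one and assemble a dataset.

    Fields are rendered at low resolution for all samples (the rendering is
    exact, not a downsample); high-resolution maps are exposed through
    :meth:`Dataset.hr_field`.  With ``out_dir`` set the dataset is also
    written to disk (PNG images, voltages CSV, manifest).
    """
    if n_train < 1 or n_test < 0:
        raise ValueError("need n_train >= 1 and n_test >= 0")
    scheme = scheme or SamplingScheme()
    config = config or DeviceConfig()
    curve = curve or VoltageStrainCurve()
    n = n_train + n_test
    arrays = sample_voltage_arrays(n, scheme, curve, config)
    volts = np.stack([a.values for a in arrays])
    commanded = np.asarray(curve(volts))
    lr = config.lr_size
    # batched rendering: both axes share the commanded-strain grids
    lr_x = render_strain_field(commanded, "X", lr, config).astype(np.float32)
    lr_y = render_strain_field(commanded, "Y", lr, config).astype(np.float32)
    split = np.array(["train"] * n_train + ["test"] * n_test)
    ds = Dataset(
        voltages=volts,
        lr_x=lr_x,
        lr_y=lr_y,
        split=split,
        config=config,
        curve=curve,
        provenance={"scheme": scheme.kind, "seed": scheme.seed},
    )
    if out_dir is not None:
        ds.save(out_dir, store_hr=store_hr)
    return ds
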