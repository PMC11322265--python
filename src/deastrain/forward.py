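"""Forward control, stage 1: voltage array -> low-resolution strain-field pair.

A single perceptron (81 -> 180 tanh -> 7200) predicts the concatenated
X and Y 3600-vectors at once; the adversarial super-resolution stage that
upscales each 60 x 60 map to 480 x 480 lives in :mod:`deastrain.srgan`.
Directly regressing 81 voltages onto flattened high-resolution images is
deliberately not provided — the two-stage split exists to avoid it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .device import DeviceConfig, VoltageArray
from .inverse import _preprocess_batch
from .nn import MLP, TrainResult
from .sampling import Dataset

__all__ = [
    "ForwardLRConfig",
    "ForwardLRModel",
    "train_forward_lr",
    "predict_lr_fields",
]


@dataclass(frozen=True)
class ForwardLRConfig:
    input_dim: int = 81
    hidden_units: int = 180
    output_dim: int = 7200  # concatenated X + Y 3600-vectors
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    momentum: float = 0.9
    val_fraction: float = 0.05
    patience: int = 30
    init: str = "pixel"  # "pixel" (per-input sparse) or "glorot"
    seed: int = 0

    def validate(self, config: DeviceConfig) -> None:
        if self.input_dim != config.grid_n**2:
            raise ValueError("input_dim must equal grid_n^2")
        if self.output_dim != 2 * config.lr_size**2:
            raise ValueError("output_dim must equal 2 * lr_size^2")
        if self.init not in ("pixel", "glorot"):
            raise ValueError("init must be 'pixel' or 'glorot'")


def _pixel_sparse_init(mlp, rng: np.random.Generator) -> None:
    """Seed hidden unit k on input voltage pixel k mod 81.

    The voltage -> image map applies the same scalar calibration
    nonlinearity to every input pixel before linear spatial mixing, so the
    network needs pixel-dedicated tanh units; a dense random first layer
    leaves gradient descent stuck in a shared smooth solution.
    """
    n_in, n_hidden, n_out = mlp.shape
    w1 = np.zeros((n_in, n_hidden), dtype=np.float32)
    b1 = np.zeros(n_hidden, dtype=np.float32)
    gains = (2.0, -3.0, 1.5, -2.5)
    for k in range(n_hidden):
        i = k % n_in
        a = gains[(k // n_in) % len(gains)] + rng.normal(0.0, 0.3)
        w1[i, k] = a
        b1[k] = rng.uniform(-2.0, 2.0)
    mlp.w1, mlp.b1 = w1, b1
    mlp.w2 = (rng.normal(0.0, 0.01, mlp.w2.shape)).astype(np.float32)
    mlp.b2 = np.zeros(n_out, dtype=np.float32)


@dataclass
class ForwardLRModel:
    """Stage-1 forward model mapping voltages to the LR image pair."""

    mlp: MLP
    x_mean: np.ndarray
    x_std: np.ndarray
    config: DeviceConfig
    model_config: ForwardLRConfig
    history: Optional[TrainResult] = None

    def predict_vectors(self, voltages: np.ndarray) -> np.ndarray:
        z = (voltages.astype(np.float32) - self.x_mean) / self.x_std
        return np.clip(self.mlp.predict(z), 0.0, 1.0)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "kind": "forward_lr",
            "model_config": asdict(self.model_config),
            "device_config": asdict(self.config),
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            x_mean=self.x_mean,
            x_std=self.x_std,
            **self.mlp.state_dict(),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ForwardLRModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        if meta.get("kind") != "forward_lr":
            raise ValueError(f"{path} is not a forward-LR checkpoint")
        mc = ForwardLRConfig(**meta["model_config"])
        dc = DeviceConfig(**meta["device_config"])
        mlp = MLP(mc.input_dim, mc.hidden_units, mc.output_dim, seed=mc.seed)
        mlp.load_state_dict({k: data[k] for k in ("w1", "b1", "w2", "b2")})
        return cls(mlp=mlp, x_mean=data["x_mean"], x_std=data["x_std"], config=dc, model_config=mc)


def train_forward_lr(
    dataset: Dataset,
    cfg: ForwardLRConfig | None = None,
    split: str = "train",
) -> ForwardLRModel:
    """Fit the voltage -> concatenated-LR-pair perceptron."""
    cfg = cfg or ForwardLRConfig()
    config = dataset.config
    cfg.validate(config)
    n = dataset.indices(split).size
    if n == 0:
        raise ValueError(f"dataset has no '{split}' samples")
    volts = dataset.subset_voltages(split).reshape(n, -1).astype(np.float32)
    vx = _preprocess_batch(dataset.lr_fields("X", split), config)
    vy = _preprocess_batch(dataset.lr_fields("Y", split), config)
    targets = np.concatenate([vx, vy], axis=1)

    x_mean = volts.mean(axis=0)
    x_std = np.maximum(volts.std(axis=0), 1e-6).astype(np.float32)

    mlp = MLP(cfg.input_dim, cfg.hidden_units, cfg.output_dim, seed=cfg.seed)
    if cfg.init == "pixel":
        _pixel_sparse_init(mlp, np.random.default_rng(cfg.seed))
    history = mlp.fit(
        (volts - x_mean) / x_std,
        targets,
        lr=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        momentum=cfg.momentum,
        val_fraction=cfg.val_fraction,
        patience=cfg.patience,
    )
    return ForwardLRModel(
        mlp=mlp,
        x_mean=x_mean,
        x_std=x_std,
        config=config,
        model_config=cfg,
        history=history,
    )


def predict_lr_fields(
    model: ForwardLRModel, voltages: VoltageArray
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict the (X, Y) low-resolution grayscale maps for one voltage array.

    Outputs are lr_size x lr_size arrays on the [0, 1] display scale; use
    :meth:`DeviceConfig.display_denormalize` for strain units.
    """
    config = model.config
    vec = voltages.flatten()[None, :]
    out = model.predict_vectors(vec)[0]
    half = config.lr_size**2
    x_map = out[:half].reshape(config.lr_size, config.lr_size)
    y_map = out[half:].reshape(config.lr_size, config.lr_size)
    return x_map, y_map
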