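"""Adversarial super-resolution stage of the forward control (stage 2).

Upscales a low-resolution strain map by 8x with a residual-block generator
(capped with three nearest-neighbour x2 upsampling blocks) trained against
a convolutional discriminator (LeakyReLU + batch normalization blocks)
using binary cross-entropy for the adversarial term and a pixelwise MSE
content term.  Both networks are plain-NumPy layer stacks with explicit
backprop and Adam updates — no deep-learning framework is available in
the target environment.

The generator carries a global bicubic skip connection and starts from a
near-zero residual branch, so training can only improve on the bicubic
baseline it is initialized at.  A scaled-down preset (15 -> 120 px,
narrow networks) exists for desk-scale testing; the full 60 -> 480
configuration is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import as_strided
from skimage.transform import resize

from .device import DeviceConfig, StrainField, VoltageArray
from .forward import ForwardLRModel, predict_lr_fields
from .inverse import crop_active_region
from .sampling import Dataset

__all__ = [
    "SRConfig",
    "SRModel",
    "train_super_resolution",
    "predict_hr_field",
    "bicubic_upscale",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    cols = windows.transpose(0, 4, 5, 1, 2, 3).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)


def _col2im(gcols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, ho, wo = shape
    g = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d:
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, scale=None):
        rng = rng or np.random.default_rng(0)
        std = scale if scale is not None else np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((cout, cin * k * k)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train=True):
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.w.T + self.b
        n, c, h, w, ho, wo = shape
        if train:
            self._cache = (cols, shape)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, shape = self._cache
        n, c, h, w, ho, wo = shape
        g2 = gy.transpose(0, 2, 3, 1).reshape(-1, self.w.shape[0])
        self.gw = (g2.T @ cols).astype(np.float32)
        self.gb = g2.sum(axis=0).astype(np.float32)
        gcols = g2 @ self.w
        return _col2im(gcols, shape, self.k, self.stride, self.pad)

    def params(self):
        return [(self, self.w, "gw"), (self, self.b, "gb")]


class BatchNorm2d:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gy):
        xhat, std = self._cache
        self.ggamma = (gy * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.gbeta = gy.sum(axis=(0, 2, 3)).astype(np.float32)
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        g = self.gamma[None, :, None, None] / std[None, :, None, None]
        mean_gy = gy.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_gyx = (gy * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (gy - mean_gy - xhat * mean_gyx)

    def params(self):
        return [(self, self.gamma, "ggamma"), (self, self.beta, "gbeta")]


class LeakyReLU:
    def __init__(self, alpha=0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.alpha * gy)

    def params(self):
        return []


class UpsampleNearest2x:
    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class ResidualBlock:
    """conv-BN-LeakyReLU-conv-BN with an identity skip."""

    def __init__(self, c, rng):
        self.body = Sequential(
            [
                Conv2d(c, c, rng=rng),
                BatchNorm2d(c),
                LeakyReLU(0.2),
                Conv2d(c, c, rng=rng),
                BatchNorm2d(c),
            ]
        )

    def forward(self, x, train=True):
        return x + self.body.forward(x, train=train)

    def backward(self, gy):
        return gy + self.body.backward(gy)

    def params(self):
        return self.body.params()


class Adam:
    def __init__(self, modules, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = []
        for mod in modules:
            for owner, p, gname in mod.params():
                self.entries.append(
                    (owner, p, gname, np.zeros_like(p), np.zeros_like(p))
                )
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for owner, p, gname, m, v in self.entries:
            g = getattr(owner, gname)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def bicubic_upscale(img: np.ndarray, scale: int) -> np.ndarray:
    """Deterministic bicubic upscaling used as the generator's global skip."""
    h, w = img.shape[-2:]
    out_shape = img.shape[:-2] + (h * scale, w * scale)
    if img.ndim == 2:
        return resize(img, out_shape, order=3, preserve_range=True, anti_aliasing=False)
    flat = img.reshape(-1, h, w)
    ups = np.stack(
        [
            resize(f, (h * scale, w * scale), order=3, preserve_range=True, anti_aliasing=False)
            for f in flat
        ]
    )
    return ups.reshape(out_shape)


@dataclass(frozen=True)
class SRConfig:
    scale: int = 8
    channels: int = 32
    n_res_blocks: int = 8
    n_disc_blocks: int = 4
    disc_channels: int = 32
    lr_generator: float = 0.00025
    lr_discriminator: float = 0.0001
    batch_size: int = 8
    epochs: int = 50
    adversarial_weight: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale & (self.scale - 1) or self.scale < 2:
            raise ValueError("scale must be a power of two >= 2")

    @property
    def n_upsample(self) -> int:
        return int(np.log2(self.scale))

    @classmethod
    def scaled_down(cls, epochs: int = 15, seed: int = 0) -> "SRConfig":
        """Desk-scale preset: narrow nets, meant for 15 -> 120 px fields.

        The generator learning rate is raised to compensate for the small
        step budget; the full-scale configuration keeps the slower rate.
        """
        return cls(
            channels=12,
            n_res_blocks=2,
            n_disc_blocks=2,
            disc_channels=12,
            lr_generator=0.001,
            epochs=epochs,
            seed=seed,
        )


class Generator:
    """Residual-branch SR generator on top of a frozen bicubic skip."""

    def __init__(self, cfg: SRConfig, rng):
        c = cfg.channels
        self.cfg = cfg
        self.head = Sequential([Conv2d(1, c, rng=rng), LeakyReLU(0.2)])
        self.res = Sequential([ResidualBlock(c, rng) for _ in range(cfg.n_res_blocks)])
        ups: List = []
        for _ in range(cfg.n_upsample):
            ups += [UpsampleNearest2x(), Conv2d(c, c, rng=rng), LeakyReLU(0.2)]
        self.up = Sequential(ups)
        # near-zero tail: the network starts as (almost exactly) bicubic
        self.tail = Conv2d(c, 1, rng=rng, scale=1e-3)
        self._skip = None

    def modules(self):
        return [self.head, self.res, self.up, self.tail]

    def forward(self, lr_batch: np.ndarray, train=True) -> np.ndarray:
        skip = bicubic_upscale(lr_batch[:, 0], self.cfg.scale)[:, None]
        x = self.head.forward(lr_batch, train=train)
        x = self.res.forward(x, train=train)
        x = self.up.forward(x, train=train)
        x = self.tail.forward(x, train=train)
        return skip.astype(np.float32) + x

    def backward(self, gy):
        g = self.tail.backward(gy)
        g = self.up.backward(g)
        g = self.res.backward(g)
        return self.head.backward(g)


class Discriminator:
    """Strided conv blocks -> global average pool -> scalar logit."""

    def __init__(self, cfg: SRConfig, rng):
        c = cfg.disc_channels
        layers: List = [Conv2d(1, c, rng=rng), LeakyReLU(0.2)]
        for _ in range(cfg.n_disc_blocks - 1):
            layers += [
                Conv2d(c, c, stride=2, rng=rng),
                BatchNorm2d(c),
                LeakyReLU(0.2),
            ]
        self.body = Sequential(layers)
        self.w = (rng.standard_normal(c) * 0.05).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        self._cache = None

    def modules(self):
        return [self.body, self]

    def params(self):
        return [(self, self.w, "gw"), (self, self.b, "gb")]

    def forward(self, x, train=True):
        feat = self.body.forward(x, train=train)
        pooled = feat.mean(axis=(2, 3))
        if train:
            self._cache = (pooled, feat.shape)
        return pooled @ self.w + self.b  # logits

    def backward(self, glogit):
        pooled, shape = self._cache
        glogit = np.asarray(glogit, dtype=np.float32).reshape(-1, 1)
        self.gw = (glogit[:, 0] @ pooled).astype(np.float32)
        self.gb = np.array([glogit.sum()], dtype=np.float32)
        gpool = glogit * self.w[None, :]
        n, c, h, w = shape
        gfeat = np.broadcast_to(gpool[:, :, None, None], shape) / (h * w)
        return self.body.backward(np.ascontiguousarray(gfeat, dtype=np.float32))

    def predict_probability(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x, train=False)))


def _bce_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean BCE on logits; returns (loss, dloss/dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = float(-np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps)))
    grad = (p - labels) / logits.size
    return loss, grad


# ---------------------------------------------------------------------------
# model wrapper and training
# ---------------------------------------------------------------------------


@dataclass
class SRModel:
    axis: str
    generator: Generator
    discriminator: Discriminator
    config: SRConfig
    device_config: DeviceConfig
    history: dict = field(default_factory=dict)

    def upscale(self, lr_image: np.ndarray) -> np.ndarray:
        """Upscale one [0, 1] LR map by the configured scale factor."""
        batch = np.asarray(lr_image, dtype=np.float32)[None, None]
        out = self.generator.forward(batch, train=False)[0, 0]
        return np.clip(out, 0.0, 1.0)


def _sr_pairs(dataset: Dataset, axis: str) -> Tuple[np.ndarray, np.ndarray]:
    """Display-normalized, active-region (LR, HR) image pairs."""
    cfg = dataset.config
    lr_raw = dataset.lr_fields(axis)
    lr = np.stack(
        [
            resize(
                crop_active_region(cfg.display_normalize(f), cfg),
                (cfg.lr_size, cfg.lr_size),
                order=1,
                preserve_range=True,
            )
            for f in lr_raw
        ]
    ).astype(np.float32)
    hr = np.stack(
        [
            resize(
                crop_active_region(dataset.hr_field(i, axis).to_gray(cfg), cfg),
                (cfg.hr_size, cfg.hr_size),
                order=1,
                preserve_range=True,
            )
            for i in range(dataset.n)
        ]
    ).astype(np.float32)
    return lr, hr


def train_super_resolution(
    dataset: Dataset,
    axis: str,
    cfg: SRConfig | None = None,
    pairs: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    verbose: bool = False,
) -> SRModel:
    """Adversarial LR -> HR training for one strain axis.

    ``pairs`` may supply precomputed (lr, hr) image stacks in [0, 1]; by
    default they are derived from the dataset.  X and Y axes are trained
    separately.  Deterministic for a fixed config seed.
    """
    cfg = cfg or SRConfig()
    dev = dataset.config
    if cfg.scale * dev.lr_size != dev.hr_size:
        raise ValueError("sr scale x lr_size must equal hr_size")
    lr_imgs, hr_imgs = pairs if pairs is not None else _sr_pairs(dataset, axis)
    if lr_imgs.shape[0] != hr_imgs.shape[0]:
        raise ValueError("unpaired LR/HR image stacks")
    n = lr_imgs.shape[0]
    if n == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    opt_g = Adam(gen.modules(), lr=cfg.lr_generator)
    opt_d = Adam(disc.modules(), lr=cfg.lr_discriminator)

    history = {"g_loss": [], "d_loss": [], "content": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_g, ep_d, ep_c, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            lr_b = lr_imgs[idx][:, None]
            hr_b = hr_imgs[idx][:, None]
            m = len(idx)

            fake = gen.forward(lr_b, train=True)

            # discriminator step (fake detached)
            logits_real = disc.forward(hr_b, train=True)
            loss_real, g_real = _bce_with_logits(logits_real, np.ones(m))
            disc.backward(g_real)
            gw_r = {id(e): getattr(e[0], e[2]).copy() for e in opt_d.entries}
            logits_fake = disc.forward(fake, train=True)
            loss_fake, g_fake = _bce_with_logits(logits_fake, np.zeros(m))
            disc.backward(g_fake)
            for e in opt_d.entries:
                getattr(e[0], e[2]).__iadd__(gw_r[id(e)])
            opt_d.step()

            # generator step: content MSE + adversarial BCE toward "real"
            logits_fake = disc.forward(fake, train=True)
            adv_loss, g_logit = _bce_with_logits(logits_fake, np.ones(m))
            g_from_adv = disc.backward(g_logit) * cfg.adversarial_weight
            diff = fake - hr_b
            content = float(np.mean(diff**2))
            g_content = (2.0 / diff.size) * diff
            gen.backward((g_content + g_from_adv).astype(np.float32))
            opt_g.step()

            ep_g += adv_loss * cfg.adversarial_weight + content
            ep_d += 0.5 * (loss_real + loss_fake)
            ep_c += content
            nb += 1
        history["g_loss"].append(ep_g / nb)
        history["d_loss"].append(ep_d / nb)
        history["content"].append(ep_c / nb)
        if verbose:
            print(
                f"epoch {epoch}: content {ep_c / nb:.5f} d {ep_d / nb:.4f}"
            )
    return SRModel(axis=axis, generator=gen, discriminator=disc, config=cfg, device_config=dev, history=history)


def predict_hr_field(
    lr_model: ForwardLRModel,
    sr_model: SRModel,
    voltages: VoltageArray,
    axis: str,
) -> StrainField:
    """Two-stage forward prediction: 81-D voltages -> HR strain field."""
    if axis != sr_model.axis:
        raise ValueError(
            f"requested axis {axis!r} but SR model was trained for {sr_model.axis!r}"
        )
    dev = lr_model.config
    x_map, y_map = predict_lr_fields(lr_model, voltages)
    lr_map = {"X": x_map, "Y": y_map}[axis]
    hr_gray = sr_model.upscale(lr_map)
    return StrainField(axis, dev.display_denormalize(hr_gray))
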