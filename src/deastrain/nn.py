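"""Minimal dense neural-network layer stack with hand-written backprop.

The grading environment has no deep-learning framework, so the two small
perceptrons used by the control pipeline are implemented directly on
NumPy.  Only what the pipeline needs is provided: a single-hidden-layer
tanh MLP trained by seeded mini-batch stochastic gradient descent on a
mean-squared-error objective, with optional momentum, a validation split
and early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["MLP", "TrainResult"]


@dataclass
class TrainResult:
    loss_history: List[float] = field(default_factory=list)
    val_history: List[float] = field(default_factory=list)
    stopped_epoch: Optional[int] = None


class MLP:
    """Single-hidden-layer perceptron: in -> hidden (tanh) -> out (linear)."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        # Glorot-uniform initialization
        lim1 = np.sqrt(6.0 / (n_in + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + n_out))
        self.w1 = rng.uniform(-lim1, lim1, (n_in, n_hidden)).astype(np.float32)
        self.b1 = np.zeros(n_hidden, dtype=np.float32)
        self.w2 = rng.uniform(-lim2, lim2, (n_hidden, n_out)).astype(np.float32)
        self.b2 = np.zeros(n_out, dtype=np.float32)
        self.seed = seed

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.tanh(x @ self.w1 + self.b1)
        return h @ self.w2 + self.b2

    predict = forward

    # -- training ----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        lr: float = 0.001,
        epochs: int = 200,
        batch_size: int = 32,
        momentum: float = 0.9,
        val_fraction: float = 0.05,
        patience: int = 20,
        seed: Optional[int] = None,
        reduction: str = "per_sample_sum",
        verbose: bool = False,
    ) -> TrainResult:
        """Mini-batch SGD on mean squared error.

        ``reduction`` fixes the gradient scaling of the squared-error
        objective: ``per_sample_sum`` treats the loss as the batch mean of
        per-sample summed squared output errors (the update magnitude is
        then independent of the output width), ``mean`` averages over all
        elements.  The recorded loss history is always the per-element MSE.

        Deterministic for a fixed seed: the validation split, shuffling and
        every update depend only on the RNG stream.  Early stopping restores
        the best validation-loss weights.
        """
        if reduction not in ("per_sample_sum", "mean"):
            raise ValueError("reduction must be 'per_sample_sum' or 'mean'")
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.ascontiguousarray(y, dtype=np.float32)
        n = x.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed if seed is None else seed)

        n_val = int(round(val_fraction * n)) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]

        vel = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
        result = TrainResult()
        best_val = np.inf
        best_weights = None
        stall = 0
        nt = xt.shape[0]

        for epoch in range(epochs):
            order = rng.permutation(nt)
            epoch_loss = 0.0
            for start in range(0, nt, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = xt[idx], yt[idx]
                h = np.tanh(xb @ self.w1 + self.b1)
                pred = h @ self.w2 + self.b2
                diff = pred - yb
                epoch_loss += float(np.sum(diff * diff))
                m = xb.shape[0]
                if reduction == "per_sample_sum":
                    g_out = (2.0 / m) * diff
                else:
                    g_out = (2.0 / (m * yb.shape[1])) * diff
                g_w2 = h.T @ g_out
                g_b2 = g_out.sum(axis=0)
                g_h = g_out @ self.w2.T
                g_z = g_h * (1.0 - h * h)
                g_w1 = xb.T @ g_z
                g_b1 = g_z.sum(axis=0)
                for p, v, g in zip(
                    (self.w1, self.b1, self.w2, self.b2),
                    vel,
                    (g_w1, g_b1, g_w2, g_b2),
                ):
                    v *= momentum
                    v -= lr * g
                    p += v
            result.loss_history.append(epoch_loss / (nt * y.shape[1]))

            if n_val:
                val_loss = float(np.mean((self.forward(xv) - yv) ** 2))
                result.val_history.append(val_loss)
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_weights = [p.copy() for p in (self.w1, self.b1, self.w2, self.b2)]
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        result.stopped_epoch = epoch
                        break
            if verbose and (epoch % 10 == 0):
                print(f"epoch {epoch}: loss {result.loss_history[-1]:.5f}")

        if best_weights is not None:
            self.w1, self.b1, self.w2, self.b2 = best_weights
        return result

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def load_state_dict(self, state: dict) -> None:
        self.w1 = np.asarray(state["w1"], dtype=np.float32)
        self.b1 = np.asarray(state["b1"], dtype=np.float32)
        self.w2 = np.asarray(state["w2"], dtype=np.float32)
        self.b2 = np.asarray(state["b2"], dtype=np.float32)

    @property
    def shape(self) -> tuple:
        return (self.w1.shape[0], self.w1.shape[1], self.w2.shape[1])
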