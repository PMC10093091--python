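"""Minimal fully-connected network core with manual backprop and Adam.

All trainable components of the pipeline (the adversarial generator and
discriminator, the patch encoder, and the patch classifier) are small
multilayer perceptrons built on this module.  The design goals are strict
determinism under a seed, per-layer freezing (transfer-learning style
re-tuning of the last k layers), and zero dependencies beyond numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "binary_cross_entropy"]


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Fully-connected net: ReLU hidden layers, configurable output.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths including input and output, e.g. ``(768, 64, 32, 1)``.
    out : {"sigmoid", "linear"}
        Output activation.
    seed : int
        Seeds He-style weight initialisation; two nets built with the same
        sizes and seed are bit-identical.
    """

    def __init__(self, sizes, out: str = "sigmoid", seed: int = 0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output layer")
        if out not in ("sigmoid", "linear"):
            raise ValueError(f"unknown output activation {out!r}")
        rng = np.random.default_rng(seed)
        self.sizes = tuple(int(s) for s in sizes)
        self.out = out
        self.W = []
        self.b = []
        for n_in, n_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / n_in)
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        # one flag per weight layer; frozen layers receive no updates
        self.trainable = [True] * len(self.W)

    @property
    def n_layers(self) -> int:
        """Number of parameterised (weight) layers."""
        return len(self.W)

    def freeze_all_but_last(self, k: int) -> None:
        """Unfreeze only the trailing ``k`` weight layers (k=0 freezes all)."""
        if not 0 <= k <= self.n_layers:
            raise ValueError(
                f"k={k} outside [0, {self.n_layers}] parameterised layers"
            )
        self.trainable = [i >= self.n_layers - k for i in range(self.n_layers)]

    # ---- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        """Return output activations; with ``cache`` also return (zs, acts)."""
        a = np.asarray(X, dtype=np.float64)
        acts = [a]
        zs = []
        last = self.n_layers - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            if i < last:
                a = _relu(z)
            elif self.out == "sigmoid":
                a = _sigmoid(z)
            else:
                a = z
            acts.append(a)
        if cache:
            return a, (zs, acts)
        return a

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (the embedding surface)."""
        _, (zs, acts) = self.forward(X, cache=True)
        return acts[-2]

    def backward(self, delta_out: np.ndarray, cache):
        """Backpropagate ``dL/dz_last`` through the cached forward pass.

        Returns ``(grads, dX)`` where grads is a list of (dW, db) per layer
        (zeros are NOT masked here — freezing is applied by the optimiser)
        and dX is the gradient with respect to the input batch.
        """
        zs, acts = cache
        grads = [None] * self.n_layers
        delta = delta_out
        for i in range(self.n_layers - 1, -1, -1):
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            grads[i] = (gW, gb)
            if i > 0:
                delta = (delta @ self.W[i].T) * (zs[i - 1] > 0)
            else:
                delta = delta @ self.W[i].T
        return grads, delta

    def params_copy(self):
        return [(W.copy(), b.copy()) for W, b in zip(self.W, self.b)]


class Adam:
    """Adam optimiser bound to one MLP; respects the net's freeze flags."""

    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.mW = [np.zeros_like(W) for W in net.W]
        self.vW = [np.zeros_like(W) for W in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, (gW, gb) in enumerate(grads):
            if not self.net.trainable[i]:
                continue
            self.mW[i] = b1 * self.mW[i] + (1 - b1) * gW
            self.vW[i] = b2 * self.vW[i] + (1 - b2) * gW * gW
            self.mb[i] = b1 * self.mb[i] + (1 - b1) * gb
            self.vb[i] = b2 * self.vb[i] + (1 - b2) * gb * gb
            self.net.W[i] -= self.lr * (self.mW[i] / corr1) / (
                np.sqrt(self.vW[i] / corr2) + self.eps)
            self.net.b[i] -= self.lr * (self.mb[i] / corr1) / (
                np.sqrt(self.vb[i] / corr2) + self.eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_binary(net: MLP, X: np.ndarray, y: np.ndarray, *, epochs: int,
               batch_size: int, lr: float, seed: int,
               class_weight: dict | None = None) -> list[float]:
    """Train a sigmoid-output MLP on binary labels; returns per-epoch loss.

    Deterministic given (net state, data, seed).  Frozen layers keep their
    initial parameters bit-identical.
    """
    if net.out != "sigmoid":
        raise ValueError("fit_binary requires a sigmoid-output net")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    n = X.shape[0]
    opt = Adam(net, lr=lr)
    rng = np.random.default_rng(seed)
    if class_weight is not None:
        w = np.where(y == 1, class_weight.get(1, 1.0),
                     class_weight.get(0, 1.0))
    else:
        w = np.ones_like(y)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb, wb = X[idx], y[idx], w[idx]
            p, cache = net.forward(xb, cache=True)
            epoch_loss += binary_cross_entropy(p, yb) * len(idx)
            delta = wb * (p - yb) / len(idx)
            grads, _ = net.backward(delta, cache)
            opt.step(grads)
        losses.append(epoch_loss / n)
    return losses
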