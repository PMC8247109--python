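"""Minimal dense neural-network layer stack with manual backprop and Adam.

Just enough machinery for the adversarial model: fully connected layers,
ReLU hidden activations, a sigmoid head, binary cross-entropy, and the Adam
optimiser.  Everything is float64 NumPy and fully deterministic given the
RNG used for initialisation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "sigmoid", "bce_loss_and_grad"]

#: Probabilities are clamped into [EPS, 1-EPS] inside losses to keep the
#: log-likelihood finite even for a saturated discriminator.
EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MLP:
    """Fully connected stack: affine -> ReLU per hidden layer, linear output.

    Parameters are stored as lists of (W, b); ``forward`` caches the
    activations needed by ``backward``.  Initialisation is uniform with
    fan-in scaling, drawn from the supplied RNG.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("need at least input and output dimensions")
        self.dims = list(dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] | None = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Map a (batch, in_dim) array to (batch, out_dim)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dims[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, expected {self.dims[0]}"
            )
        acts = [x]
        h = x
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if k < self.n_layers - 1:
                h = relu(h)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backprop ``dLoss/dOutput`` through the cached forward pass.

        Fills ``self.grad_w`` / ``self.grad_b`` and returns ``dLoss/dInput``.
        """
        if self._cache is None:
            raise RuntimeError("call forward(..., cache=True) before backward()")
        acts = self._cache
        self.grad_w = [np.zeros_like(w) for w in self.weights]
        self.grad_b = [np.zeros_like(b) for b in self.biases]
        g = np.asarray(grad_out, dtype=float)
        for k in range(self.n_layers - 1, -1, -1):
            if k < self.n_layers - 1:
                g = g * (acts[k + 1] > 0)  # ReLU gate
            self.grad_w[k] = acts[k].T @ g
            self.grad_b[k] = g.sum(axis=0)
            g = g @ self.weights[k].T
        return g

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def grads(self) -> list[np.ndarray]:
        return self.grad_w + self.grad_b

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{k}"] = w
            out[f"b{k}"] = b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in range(self.n_layers):
            w = np.asarray(state[f"W{k}"], dtype=float)
            b = np.asarray(state[f"b{k}"], dtype=float)
            if w.shape != self.weights[k].shape or b.shape != self.biases[k].shape:
                raise ValueError(f"layer {k} shape mismatch in checkpoint")
            self.weights[k] = w
            self.biases[k] = b

    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.dims = list(self.dims)
        clone.weights = [w.copy() for w in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        clone._cache = None
        return clone


def bce_loss_and_grad(
    probs: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the probabilities."""
    p = np.clip(probs, EPS, 1.0 - EPS)
    t = np.asarray(targets, dtype=float)
    n = p.shape[0]
    loss = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    grad = (p - t) / (p * (1 - p)) / n
    return loss, grad


class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
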