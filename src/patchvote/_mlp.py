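"""Minimal fully-connected softmax network trained with Adam.

Weights are plain numpy arrays, so initialization, per-epoch updates,
best-epoch snapshots and npz serialization are all exact and seeded —
the properties the patch-classifier contract needs (deterministic
init-time predictions, bit-identical save/reload).
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probabilities: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probabilities, 1e-12, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


class SoftmaxMLP:
    """ReLU hidden layers, softmax output, Adam optimizer.

    Parameters
    ----------
    layer_sizes : sequence of int
        ``[n_features, hidden..., n_classes]``.
    seed : int
        Seeds the Glorot-uniform weight initialization.
    """

    def __init__(self, layer_sizes, seed: int = 0, weight_decay: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layer_sizes = [int(s) for s in layer_sizes]
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        self.seed = int(seed)
        self.weight_decay = float(weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        rng = np.random.default_rng(self.seed)
        self.weights, self.biases = [], []
        for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))
        self._reset_adam()

    def _reset_adam(self) -> None:
        self._m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._t = 0

    # ---- forward / loss -------------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        activations = [X]
        a = X
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = softmax(z) if k == len(self.weights) - 1 else np.maximum(z, 0.0)
            activations.append(a)
        return activations

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def loss(self, X: np.ndarray, onehot: np.ndarray) -> float:
        return cross_entropy(self.predict_proba(X), onehot)

    # ---- training -------------------------------------------------------
    def _step(self, X: np.ndarray, onehot: np.ndarray, lr: float) -> None:
        acts = self._forward(X)
        n = X.shape[0]
        delta = (acts[-1] - onehot) / n  # softmax + CE gradient
        grads_w, grads_b = [], []
        for k in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[k].T @ delta + self.weight_decay * self.weights[k])
            grads_b.append(delta.sum(axis=0))
            if k > 0:
                delta = (delta @ self.weights[k].T) * (acts[k] > 0)
        grads = list(reversed(grads_w)) + list(reversed(grads_b))
        params = self.weights + self.biases
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def train_epoch(self, X: np.ndarray, onehot: np.ndarray, lr: float,
                    batch_size: int, rng: np.random.Generator) -> None:
        order = rng.permutation(X.shape[0])
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            self._step(X[idx], onehot[idx], lr)

    # ---- (de)serialization ----------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]

    def set_weights(self, flat: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [np.array(w, dtype=float) for w in flat[:k]]
        self.biases = [np.array(b, dtype=float) for b in flat[k:]]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"layer_sizes": np.array(self.layer_sizes), "seed": np.array(self.seed)}
        for i, w in enumerate(self.weights):
            out[f"W{i}"] = w
        for i, b in enumerate(self.biases):
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state_dict(cls, state) -> "SoftmaxMLP":
        sizes = [int(s) for s in np.asarray(state["layer_sizes"])]
        net = cls(sizes, seed=int(np.asarray(state["seed"])))
        n = len(sizes) - 1
        net.set_weights([np.asarray(state[f"W{i}"]) for i in range(n)]
                        + [np.asarray(state[f"b{i}"]) for i in range(n)])
        return net
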