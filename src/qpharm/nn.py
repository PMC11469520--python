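"""A small fully-connected network with hand-written backprop and Adam.

Used as the trainable head of both the point predictor and the Q-function.
Deliberately minimal: dense layers, ReLU/tanh hidden activations, linear or
sigmoid output, mean-squared-error or binary-cross-entropy loss, full
determinism under a seed.
"""

from __future__ import annotations

import numpy as np

_ACTS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Multilayer perceptron with Glorot init and an Adam optimizer."""

    def __init__(self, sizes: list[int], activation: str = "relu",
                 out: str = "linear", seed: int = 0, zero_init: bool = False):
        self.sizes = list(sizes)
        self.activation = activation
        self.out = out
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            if zero_init:
                w = np.zeros((n_in, n_out))
            else:
                limit = np.sqrt(6.0 / (n_in + n_out))
                w = rng.uniform(-limit, limit, size=(n_in, n_out))
            self.W.append(w)
            self.b.append(np.zeros(n_out))
        self._adam_state = None

    # ---- forward -----------------------------------------------------
    def _forward(self, X: np.ndarray):
        act, _ = _ACTS[self.activation]
        a = np.asarray(X, dtype=float)
        zs, acts = [], [a]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            if i < len(self.W) - 1:
                a = act(z)
            else:
                a = sigmoid(z) if self.out == "sigmoid" else z
            acts.append(a)
        return zs, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(X))[1][-1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Activations of the final hidden layer (the embedding)."""
        return self._forward(np.atleast_2d(X))[1][-2]

    # ---- training ----------------------------------------------------
    def _grads(self, X, Y, loss: str):
        _, dact = _ACTS[self.activation]
        zs, acts = self._forward(X)
        n = X.shape[0]
        yhat = acts[-1]
        if loss == "bce":
            if self.out != "sigmoid":
                raise ValueError("bce loss requires a sigmoid output")
            eps = 1e-12
            L = -np.mean(Y * np.log(yhat + eps) + (1 - Y) * np.log(1 - yhat + eps))
            delta = (yhat - Y) / (n * Y.shape[1])  # dL/dz for sigmoid+bce
        elif loss == "mse":
            diff = yhat - Y
            L = float(np.mean(diff ** 2))
            delta = 2.0 * diff / diff.size
            if self.out == "sigmoid":
                delta = delta * yhat * (1 - yhat)
        else:
            raise ValueError(f"unknown loss {loss!r}")
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in reversed(range(len(self.W))):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * dact(zs[i - 1], acts[i])
        return float(L), gW, gb

    def fit(self, X, Y, loss: str = "mse", epochs: int = 100,
            batch_size: int | None = None, lr: float = 1e-3,
            seed: int = 0, reset_optimizer: bool = False) -> list[float]:
        """Adam on (X, Y); returns the per-epoch loss trace."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        rng = np.random.default_rng(seed)
        if self._adam_state is None or reset_optimizer:
            self._adam_state = {
                "t": 0,
                "mW": [np.zeros_like(w) for w in self.W],
                "vW": [np.zeros_like(w) for w in self.W],
                "mb": [np.zeros_like(b) for b in self.b],
                "vb": [np.zeros_like(b) for b in self.b],
            }
        st = self._adam_state
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        bs = n if batch_size is None else min(batch_size, n)
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss, nb = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                L, gW, gb = self._grads(X[idx], Y[idx], loss)
                if not np.isfinite(L):
                    raise FloatingPointError("training loss became non-finite")
                epoch_loss += L
                nb += 1
                st["t"] += 1
                corr1 = 1 - b1 ** st["t"]
                corr2 = 1 - b2 ** st["t"]
                for i in range(len(self.W)):
                    for g, w, m, v in ((gW[i], self.W[i], st["mW"][i], st["vW"][i]),
                                       (gb[i], self.b[i], st["mb"][i], st["vb"][i])):
                        m *= b1
                        m += (1 - b1) * g
                        v *= b2
                        v += (1 - b2) * g * g
                        w -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)
            trace.append(epoch_loss / max(nb, 1))
        return trace

    # ---- (de)serialization -------------------------------------------
    def state_dict(self) -> dict:
        return {
            "sizes": self.sizes, "activation": self.activation, "out": self.out,
            "W": [w.tolist() for w in self.W], "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        net = cls(state["sizes"], state["activation"], state["out"], seed=0)
        net.W = [np.array(w, dtype=float) for w in state["W"]]
        net.b = [np.array(b, dtype=float) for b in state["b"]]
        return net

    def copy(self) -> "MLP":
        return MLP.from_state_dict(self.state_dict())
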