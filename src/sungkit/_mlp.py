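"""A small dense softmax network trained with Adam.

Feed-forward classifier with 1-3 ReLU hidden layers, inverted dropout on the
input and on every hidden layer, glorot-uniform initialization, softmax
output with (sample-weighted) cross-entropy loss, mini-batches of 128 and
Adam at learning rate 0.001. Epochs are a hyperparameter; no early stopping.
"""

from __future__ import annotations

import numpy as np


class DenseSoftmaxNet:
    def __init__(
        self,
        hidden: tuple[int, ...] = (32,),
        epochs: int = 100,
        dropout: float = 0.2,
        input_dropout: float = 0.1,
        batch_size: int = 128,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        if not 1 <= len(hidden) <= 3:
            raise ValueError("1 to 3 hidden layers supported")
        self.hidden = tuple(int(h) for h in hidden)
        self.epochs = int(epochs)
        self.dropout = float(dropout)
        self.input_dropout = float(input_dropout)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.seed = int(seed)

    # -- internals ----------------------------------------------------------
    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator):
        sizes = [n_in, *self.hidden, n_out]
        self.W_, self.b_ = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (a + b))  # glorot uniform
            self.W_.append(rng.uniform(-limit, limit, size=(a, b)))
            self.b_.append(np.zeros(b))

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward(self, X, rng=None):
        """Forward pass; with rng, applies inverted dropout and caches masks."""
        acts, masks = [X], []
        h = X
        if rng is not None and self.input_dropout > 0:
            m = (rng.random(h.shape) >= self.input_dropout) / (1 - self.input_dropout)
            h = h * m
            acts[0] = h
            masks.append(m)
        else:
            masks.append(None)
        for layer, (W, b) in enumerate(zip(self.W_, self.b_)):
            z = h @ W + b
            if layer < len(self.W_) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    m = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = self._softmax(z)
        return h, acts, masks

    # -- API ----------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        classes, y_idx = np.unique(y, return_inverse=True)
        self.classes_ = classes
        n, d = X.shape
        k = len(classes)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._init_params(d, k, rng)

        # Adam state
        mW = [np.zeros_like(W) for W in self.W_]
        vW = [np.zeros_like(W) for W in self.W_]
        mb = [np.zeros_like(b) for b in self.b_]
        vb = [np.zeros_like(b) for b in self.b_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        onehot = np.zeros((n, k))
        onehot[np.arange(n), y_idx] = 1.0

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                Xb, Yb, wb = X[batch], onehot[batch], w[batch]
                probs, acts, masks = self._forward(Xb, rng=rng)
                # dL/dz at output for weighted mean CE
                delta = (probs - Yb) * (wb / wb.sum())[:, None]
                grads_W, grads_b = [], []
                for layer in range(len(self.W_) - 1, -1, -1):
                    a_prev = acts[layer]
                    grads_W.append(a_prev.T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = delta @ self.W_[layer].T
                        delta = delta * (acts[layer] > 0)  # ReLU grad (post-dropout cache)
                        if masks[layer] is not None:
                            delta = delta * masks[layer]
                grads_W.reverse()
                grads_b.reverse()
                step += 1
                for layer in range(len(self.W_)):
                    for g, p, m, v in (
                        (grads_W[layer], self.W_, mW, vW),
                        (grads_b[layer], self.b_, mb, vb),
                    ):
                        m[layer] = b1 * m[layer] + (1 - b1) * g
                        v[layer] = b2 * v[layer] + (1 - b2) * g * g
                        mhat = m[layer] / (1 - b1**step)
                        vhat = v[layer] / (1 - b2**step)
                        p[layer] = p[layer] - self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward(np.asarray(X, dtype=float), rng=None)
        return probs
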