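"""Minimal stacked-LSTM regressor in numpy.

Implements the reference one-step-ahead forecaster: stacked LSTM layers, a
dropout mask on the final hidden state, and a dense head, trained with Adam
on mean-squared error with validation-based early stopping.  Gradients are
hand-written backpropagation through time and are verified against central
finite differences in the test suite.

This is intentionally small: fixed-length input sequences, full-sequence
BPTT, no cuDNN-style fusions.  For the window sizes used here (24 steps, 8
features) it trains in seconds on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


@dataclass
class _Layer:
    W: np.ndarray   # (d_in, 4H) input->gates
    U: np.ndarray   # (H, 4H)    hidden->gates
    b: np.ndarray   # (4H,)      gate bias; forget slice initialised to 1


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class LSTMRegressor:
    """Stacked LSTM -> dropout -> dense, predicting a vector from a sequence."""

    def __init__(
        self,
        n_features: int,
        hidden: int = 64,
        n_layers: int = 2,
        n_outputs: int = 2,
        dropout: float = 0.2,
        seed: int = 0,
    ) -> None:
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.dropout = dropout
        self.layers: list[_Layer] = []
        d = n_features
        for _ in range(n_layers):
            W = rng.normal(0.0, 1.0 / np.sqrt(d), (d, 4 * hidden))
            U = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, 4 * hidden))
            b = np.zeros(4 * hidden)
            b[hidden:2 * hidden] = 1.0  # forget-gate bias
            self.layers.append(_Layer(W, U, b))
            d = hidden
        self.Wo = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, n_outputs))
        self.bo = np.zeros(n_outputs)
        self._rng = rng

    # -- parameter flattening (Adam state, gradient checking) -------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers:
            out += [lay.W, lay.U, lay.b]
        out += [self.Wo, self.bo]
        return out

    def _forward_layer(self, lay: _Layer, X: np.ndarray):
        B, T, _ = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        Hs = np.empty((B, T, H))
        for t in range(T):
            z = X[:, t] @ lay.W + h @ lay.U + lay.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            cache.append((X[:, t], h_prev, c_prev, i, f, g, o, c, tc))
        return Hs, cache

    def forward(self, X: np.ndarray, train: bool = False):
        """Returns predictions (B, n_out) and the cache for backprop."""
        caches = []
        inp = X
        for lay in self.layers:
            Hs, cache = self._forward_layer(lay, inp)
            caches.append(cache)
            inp = Hs
        hT = inp[:, -1]
        if train and self.dropout > 0:
            mask = (self._rng.random(hT.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(hT)
        y = (hT * mask) @ self.Wo + self.bo
        return y, (X, caches, hT, mask)

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(np.asarray(X, dtype=float), train=False)
        return y

    def _backward_layer(self, lay: _Layer, cache, dHs: np.ndarray):
        """dHs: (B, T, H) gradient wrt this layer's output sequence."""
        B, T, H = dHs.shape
        dW = np.zeros_like(lay.W)
        dU = np.zeros_like(lay.U)
        db = np.zeros_like(lay.b)
        dX = np.empty((B, T, lay.W.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c, tc = cache[t]
            dh = dHs[:, t] + dh_next
            do_ = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do_ * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ lay.W.T
            dh_next = dz @ lay.U.T
        return dW, dU, db, dX

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, train: bool = True):
        """MSE loss and gradients in the order of :meth:`parameters`."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        pred, (_, caches, hT, mask) = self.forward(X, train=train)
        diff = pred - y
        loss = float(np.mean(diff * diff))
        dpred = 2.0 * diff / diff.size

        hT_drop = hT * mask
        dWo = hT_drop.T @ dpred
        dbo = dpred.sum(axis=0)
        dhT = (dpred @ self.Wo.T) * mask

        B, T, _ = X.shape
        grads_per_layer = []
        dHs = np.zeros((B, T, self.hidden))
        dHs[:, -1] = dhT
        for li in range(len(self.layers) - 1, -1, -1):
            dW, dU, db, dX = self._backward_layer(self.layers[li], caches[li], dHs)
            grads_per_layer.append((dW, dU, db))
            dHs = dX  # gradient wrt the lower layer's full output sequence
        grads = []
        for dW, dU, db in reversed(grads_per_layer):
            grads += [dW, dU, db]
        grads += [dWo, dbo]
        return loss, grads

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self.predict(X)
        return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        *,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 150,
        patience: int = 10,
        seed: int = 0,
    ) -> TrainingHistory:
        """Adam + early stopping on validation loss; restores best weights."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t_adam = 0
        rng = np.random.default_rng(seed)
        hist = TrainingHistory()
        best_val = np.inf
        best_weights = [p.copy() for p in params]
        stale = 0
        n = len(X)
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(X[idx], y[idx], train=True)
                epoch_loss += loss * len(idx)
                t_adam += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    mhat = mi / (1 - b1 ** t_adam)
                    vhat = vi / (1 - b2 ** t_adam)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            hist.train_loss.append(epoch_loss / n)
            val = self.evaluate(X_val, y_val)
            hist.val_loss.append(val)
            if val < best_val - 1e-12:
                best_val = val
                best_weights = [p.copy() for p in params]
                hist.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    hist.stopped_epoch = epoch
                    break
        else:
            hist.stopped_epoch = max_epochs
        for p, w in zip(params, best_weights):
            p[...] = w
        return hist

    # -- native serialization --------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for i, lay in enumerate(self.layers):
            arrays[f"W{i}"] = lay.W
            arrays[f"U{i}"] = lay.U
            arrays[f"b{i}"] = lay.b
        arrays["Wo"] = self.Wo
        arrays["bo"] = self.bo
        np.savez(path, n_layers=len(self.layers), hidden=self.hidden,
                 dropout=self.dropout, **arrays)

    @classmethod
    def load(cls, path) -> "LSTMRegressor":
        data = np.load(path)
        n_layers = int(data["n_layers"])
        hidden = int(data["hidden"])
        n_features = data["W0"].shape[0]
        n_outputs = data["Wo"].shape[1]
        model = cls(n_features, hidden=hidden, n_layers=n_layers,
                    n_outputs=n_outputs, dropout=float(data["dropout"]))
        for i, lay in enumerate(model.layers):
            lay.W = data[f"W{i}"]
            lay.U = data[f"U{i}"]
            lay.b = data[f"b{i}"]
        model.Wo = data["Wo"]
        model.bo = data["bo"]
        return model
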