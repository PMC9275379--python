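"""Two-layer stacked LSTM sequence classifier, in numpy.

Feature sequences are short (one vector per 1 s window), so a direct
batched implementation with full backpropagation through time is cheap.
The final hidden state of the second layer feeds a dense softmax head.
Training uses Adam with a class-weighted cross-entropy and a
reduce-on-plateau learning-rate schedule (factor 0.5 down to a floor
when the validation loss stops improving).
"""
from __future__ import annotations

import numpy as np

from .core import Adam, glorot_init, sigmoid, softmax, weighted_softmax_ce


class _LstmLayer:
    def __init__(self, n_in: int, units: int, rng: np.random.Generator) -> None:
        self.n_in, self.units = n_in, units
        self.params = {
            "wx": glorot_init(rng, (n_in, 4 * units), n_in, 4 * units),
            "wh": glorot_init(rng, (units, 4 * units), units, 4 * units),
            "b": np.zeros(4 * units),
        }
        self.params["b"][units : 2 * units] = 1.0  # forget-gate bias

    def forward(self, x: np.ndarray):
        """x: (N, T, F) -> h sequence (N, T, U) plus BPTT cache."""
        n, t_len, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        hs = np.zeros((n, t_len, u))
        cache = []
        wx, wh, b = self.params["wx"], self.params["wh"], self.params["b"]
        for t in range(t_len):
            a = x[:, t] @ wx + h @ wh + b
            i = sigmoid(a[:, :u])
            f = sigmoid(a[:, u : 2 * u])
            g = np.tanh(a[:, 2 * u : 3 * u])
            o = sigmoid(a[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        return hs, cache

    def backward(self, cache, dh_ext: np.ndarray):
        """dh_ext: (N, T, U) external gradient on each hidden state."""
        n, t_len, u = dh_ext.shape
        wx, wh = self.params["wx"], self.params["wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros(4 * u)
        dx = np.zeros((n, t_len, self.n_in))
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for t in range(t_len - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh_ext[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dwx += x_t.T @ da
            dwh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ wx.T
            dh_next = da @ wh.T
        return dx, {"wx": dwx, "wh": dwh, "b": db}


class StackedLstm:
    """Stacked (two-layer by default) LSTM with a softmax head."""

    def __init__(self, n_features: int, units: tuple[int, int] = (80, 30),
                 n_classes: int = 2, seed: int = 0) -> None:
        self.n_features = n_features
        self.units = tuple(units)
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers = []
        n_in = n_features
        for u in self.units:
            self.layers.append(_LstmLayer(n_in, u, rng))
            n_in = u
        self.out_w = glorot_init(rng, (n_in, n_classes), n_in, n_classes)
        self.out_b = np.zeros(n_classes)
        self.history: list[dict[str, float]] = []

    # flattened parameter dict so one Adam instance covers everything
    def _params(self) -> dict[str, np.ndarray]:
        params = {}
        for li, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                params[f"l{li}_{k}"] = v
        params["out_w"] = self.out_w
        params["out_b"] = self.out_b
        return params

    def forward(self, x: np.ndarray):
        caches = []
        h = np.asarray(x, dtype=float)
        for layer in self.layers:
            h, cache = layer.forward(h)
            caches.append(cache)
        last = h[:, -1]
        logits = last @ self.out_w + self.out_b
        return logits, (caches, last, h.shape)

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        caches, last, top_shape = cache
        grads = {
            "out_w": last.T @ dlogits,
            "out_b": dlogits.sum(axis=0),
        }
        dh_ext = np.zeros(top_shape)
        dh_ext[:, -1] = dlogits @ self.out_w.T
        for li in range(len(self.layers) - 1, -1, -1):
            dx, layer_grads = self.layers[li].backward(caches[li], dh_ext)
            for k, v in layer_grads.items():
                grads[f"l{li}_{k}"] = v
            dh_ext = dx
        return grads

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        sample_weights: np.ndarray,
        epochs: int = 100,
        batch_size: int = 32,
        lr_start: float = 1e-3,
        lr_floor: float = 1e-4,
        lr_decay_factor: float = 0.5,
        patience: int = 5,
        min_delta: float = 1e-4,
        val_indices: np.ndarray | None = None,
    ) -> list[dict[str, float]]:
        """Train with Adam; `val_indices` drive the plateau schedule."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        sample_weights = np.asarray(sample_weights, dtype=float)
        all_idx = np.arange(x.shape[0])
        if val_indices is None or len(val_indices) == 0:
            train_idx, val_idx = all_idx, all_idx
        else:
            val_idx = np.asarray(val_indices, dtype=int)
            train_idx = np.setdiff1d(all_idx, val_idx)
            if train_idx.size == 0:
                train_idx = all_idx
        rng = np.random.default_rng(self.seed + 1)
        opt = Adam(lr=lr_start)
        params = self._params()
        best_val = np.inf
        stall = 0
        for epoch in range(epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for start in range(0, perm.size, batch_size):
                idx = perm[start : start + batch_size]
                logits, cache = self.forward(x[idx])
                loss, dlogits = weighted_softmax_ce(logits, y[idx], sample_weights[idx])
                grads = self.backward(cache, dlogits)
                opt.step(params, grads)
                losses.append(loss)
            logits, _ = self.forward(x[val_idx])
            val_loss, _ = weighted_softmax_ce(logits, y[val_idx], sample_weights[val_idx])
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)),
                 "val_loss": val_loss, "lr": opt.lr}
            )
            if val_loss < best_val - min_delta:
                best_val = val_loss
                stall = 0
            else:
                stall += 1
                if stall >= patience and opt.lr > lr_floor:
                    opt.lr = max(lr_floor, opt.lr * lr_decay_factor)
                    stall = 0
        return self.history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(np.asarray(x, dtype=float))
        return softmax(logits)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = dict(self._params())
        arrays["_meta"] = np.array(
            [self.n_features, *self.units, self.n_classes, self.seed], dtype=np.int64
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "StackedLstm":
        data = np.load(path)
        m = data["_meta"]
        net = cls(n_features=int(m[0]), units=tuple(int(u) for u in m[1:-2]),
                  n_classes=int(m[-2]), seed=int(m[-1]))
        params = net._params()
        for k in params:
            params[k][...] = data[k]
        return net
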