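"""Small 3D convolutional network for ROI frame windows, in numpy.

Architecture (default): spatial average-pool (1,2,2) to halve the 64x64
frames, then two conv blocks (3x3x3 kernels, 8 and 16 filters, ReLU,
2x2x2 max-pool), a 64-unit dense layer with dropout 0.5, and a 2-class
softmax head.  Convolutions are computed as 27 shifted matrix products,
which keeps memory bounded and leans on BLAS.  Training uses Adam on a
class-weighted cross-entropy and is reproducible for a fixed seed.
"""
from __future__ import annotations

import numpy as np

from .core import Adam, he_init, softmax, weighted_softmax_ce

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]

_LEAK = 0.01  # leaky-ReLU slope; avoids dead-unit collapse on near-constant input


def _leaky(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, _LEAK * z)


def _dleaky(mask: np.ndarray, dz: np.ndarray) -> np.ndarray:
    return np.where(mask, dz, _LEAK * dz)


def _flat_weights(w: np.ndarray, dtype) -> np.ndarray:
    """(F, C, 3, 3, 3) -> (F, 27*C) in the im2col column order."""
    f, c = w.shape[:2]
    return np.ascontiguousarray(
        w.transpose(0, 2, 3, 4, 1).reshape(f, 27 * c), dtype=dtype
    )


def _im2col(x: np.ndarray):
    """x:(N,C,D,H,W) -> columns (N, 27*C, D*H*W) for a same-padded 3x3x3."""
    n, c, d, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    col = np.empty((n, 27 * c, d * h * wd), dtype=x.dtype)
    for o, (i, j, k) in enumerate(_OFFSETS):
        col[:, o * c : (o + 1) * c] = xp[:, :, i : i + d, j : j + h, k : k + wd].reshape(n, c, -1)
    return col


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3x3 convolution as one GEMM over im2col columns."""
    n, c, d, h, wd = x.shape
    f = w.shape[0]
    col = _im2col(x)
    out = np.matmul(_flat_weights(w, x.dtype)[None], col).reshape(n, f, d, h, wd)
    out += b[None, :, None, None, None].astype(x.dtype)
    return out, (col, x.shape)


def _conv3d_backward(cache, w: np.ndarray, dout: np.ndarray):
    col, x_shape = cache
    n, c, d, h, wd = x_shape
    f = w.shape[0]
    doutf = dout.reshape(n, f, -1)
    dw_flat = np.matmul(doutf, col.transpose(0, 2, 1)).sum(axis=0)
    dw = dw_flat.reshape(f, 3, 3, 3, c).transpose(0, 4, 1, 2, 3)
    db = doutf.sum(axis=(0, 2))
    dcol = np.matmul(_flat_weights(w, dout.dtype).T[None], doutf)
    dxp = np.zeros((n, c, d + 2, h + 2, wd + 2), dtype=dout.dtype)
    for o, (i, j, k) in enumerate(_OFFSETS):
        dxp[:, :, i : i + d, j : j + h, k : k + wd] += dcol[
            :, o * c : (o + 1) * c
        ].reshape(n, c, d, h, wd)
    dx = dxp[:, :, 1:-1, 1:-1, 1:-1]
    return dx, dw, db


def _maxpool(x: np.ndarray):
    """2x2x2 max pooling; odd trailing elements are trimmed."""
    n, c, d, h, w = x.shape
    d2, h2, w2 = d // 2, h // 2, w // 2
    xt = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2]
    xr = xt.reshape(n, c, d2, 2, h2, 2, w2, 2)
    out = xr.max(axis=(3, 5, 7))
    return out, (x.shape, xr, out)


def _maxpool_backward(cache, dout: np.ndarray) -> np.ndarray:
    x_shape, xr, out = cache
    mask = xr == out[:, :, :, None, :, None, :, None]
    g = mask * dout[:, :, :, None, :, None, :, None]
    n, c, d, h, w = x_shape
    d2, h2, w2 = d // 2, h // 2, w // 2
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = g.reshape(n, c, d2 * 2, h2 * 2, w2 * 2)
    return dx


def _avgpool_spatial(x: np.ndarray, p: int):
    n, c, d, h, w = x.shape
    h2, w2 = h // p, w // p
    xt = x[:, :, :, : h2 * p, : w2 * p]
    out = xt.reshape(n, c, d, h2, p, w2, p).mean(axis=(4, 6))
    return out, x.shape


def _avgpool_spatial_backward(x_shape, p: int, dout: np.ndarray) -> np.ndarray:
    n, c, d, h, w = x_shape
    h2, w2 = h // p, w // p
    dx = np.zeros(x_shape, dtype=dout.dtype)
    spread = np.repeat(np.repeat(dout, p, axis=3), p, axis=4) / (p * p)
    dx[:, :, :, : h2 * p, : w2 * p] = spread
    return dx


class Conv3dNet:
    """Two-block 3D CNN with a dense head; trained with Adam."""

    def __init__(
        self,
        in_shape: tuple[int, int, int],
        filters: tuple[int, int] = (8, 16),
        dense_units: int = 64,
        n_classes: int = 2,
        dropout: float = 0.5,
        spatial_prepool: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        self.in_shape = tuple(in_shape)
        self.filters = tuple(filters)
        self.dense_units = dense_units
        self.n_classes = n_classes
        self.dropout = dropout
        self.spatial_prepool = spatial_prepool
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f1, f2 = self.filters
        d, h, w = self.in_shape
        h //= spatial_prepool
        w //= spatial_prepool
        d1, h1, w1 = d // 2, h // 2, w // 2
        d2, h2, w2 = d1 // 2, h1 // 2, w1 // 2
        self._flat = f2 * d2 * h2 * w2
        self.params: dict[str, np.ndarray] = {
            "conv1_w": he_init(rng, (f1, 1, 3, 3, 3), 27),
            "conv1_b": np.zeros(f1),
            "conv2_w": he_init(rng, (f2, f1, 3, 3, 3), 27 * f1),
            "conv2_b": np.zeros(f2),
            "dense_w": he_init(rng, (self._flat, dense_units), self._flat),
            "dense_b": np.zeros(dense_units),
            "out_w": he_init(rng, (dense_units, n_classes), dense_units),
            "out_b": np.zeros(n_classes),
        }
        self.history: list[dict[str, float]] = []

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool, rng=None):
        cache: dict = {}
        x = x.astype(self.dtype, copy=False)[:, None]  # (N,1,D,H,W)
        a0, cache["pre_shape"] = _avgpool_spatial(x, self.spatial_prepool)
        z1, cache["xp1"] = _conv3d_forward(
            a0, self.params["conv1_w"], self.params["conv1_b"]
        )
        r1 = _leaky(z1)
        cache["r1_mask"] = z1 > 0
        p1, cache["pool1"] = _maxpool(r1)
        z2, cache["xp2"] = _conv3d_forward(
            p1, self.params["conv2_w"], self.params["conv2_b"]
        )
        r2 = _leaky(z2)
        cache["r2_mask"] = z2 > 0
        p2, cache["pool2"] = _maxpool(r2)
        flat = p2.reshape(p2.shape[0], -1)
        cache["flat"] = flat
        cache["p2_shape"] = p2.shape
        zd = flat @ self.params["dense_w"].astype(self.dtype) + self.params["dense_b"]
        rd = _leaky(zd)
        cache["rd_mask"] = zd > 0
        if train and self.dropout > 0:
            keep = (rng.random(rd.shape) >= self.dropout).astype(self.dtype)
            rd = rd * keep / (1.0 - self.dropout)
            cache["drop"] = keep
        cache["rd"] = rd
        logits = rd @ self.params["out_w"].astype(self.dtype) + self.params["out_b"]
        return logits.astype(float), cache

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(self.dtype)
        grads["out_w"] = cache["rd"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        drd = dlogits @ self.params["out_w"].T.astype(self.dtype)
        if "drop" in cache:
            drd = drd * cache["drop"] / (1.0 - self.dropout)
        dzd = _dleaky(cache["rd_mask"], drd)
        grads["dense_w"] = cache["flat"].T @ dzd
        grads["dense_b"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["dense_w"].T.astype(self.dtype)
        dp2 = dflat.reshape(cache["p2_shape"])
        dr2 = _maxpool_backward(cache["pool2"], dp2)
        dz2 = _dleaky(cache["r2_mask"], dr2)
        dp1, dw2, db2 = _conv3d_backward(cache["xp2"], self.params["conv2_w"], dz2)
        grads["conv2_w"], grads["conv2_b"] = dw2, db2
        dr1 = _maxpool_backward(cache["pool1"], dp1)
        dz1 = _dleaky(cache["r1_mask"], dr1)
        _, dw1, db1 = _conv3d_backward(cache["xp1"], self.params["conv1_w"], dz1)
        grads["conv1_w"], grads["conv1_b"] = dw1, db1
        return {k: np.asarray(v, dtype=float) for k, v in grads.items()}

    # -- training / inference ----------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        sample_weights: np.ndarray,
        epochs: int = 50,
        batch_size: int = 8,
        lr: float = 1e-3,
    ) -> list[dict[str, float]]:
        x = np.asarray(x)
        y = np.asarray(y, dtype=int)
        sample_weights = np.asarray(sample_weights, dtype=float)
        rng = np.random.default_rng(self.seed + 1)
        opt = Adam(lr=lr)
        n = x.shape[0]
        for epoch in range(epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                logits, cache = self._forward(x[idx], train=True, rng=rng)
                loss, dlogits = weighted_softmax_ce(logits, y[idx], sample_weights[idx])
                grads = self._backward(cache, dlogits)
                opt.step(self.params, grads)
                losses.append(loss)
            self.history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        return self.history

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        x = np.asarray(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[start : start + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        meta = np.array(
            [self.in_shape[0], self.in_shape[1], self.in_shape[2],
             self.filters[0], self.filters[1], self.dense_units, self.n_classes,
             self.spatial_prepool, self.seed], dtype=np.int64,
        )
        np.savez(path, _meta=meta, _dropout=np.array([self.dropout]), **self.params)

    @classmethod
    def load(cls, path) -> "Conv3dNet":
        data = np.load(path)
        m = data["_meta"]
        net = cls(
            in_shape=(int(m[0]), int(m[1]), int(m[2])),
            filters=(int(m[3]), int(m[4])),
            dense_units=int(m[5]),
            n_classes=int(m[6]),
            dropout=float(data["_dropout"][0]),
            spatial_prepool=int(m[7]),
            seed=int(m[8]),
        )
        for key in net.params:
            net.params[key] = data[key]
        return net
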