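"""Stage 2: a 1-D convolutional smoother over provisional probabilities.

The temporal model maps the preceding ``lookback`` minutes of provisional
(stage-1) probability onto the probability that the *next* minute is in
work mode.  Structure is fixed: 3 convolution layers and 2 fully connected
layers; the first two convolutions are followed by max pooling and the
third by global average pooling; hidden activations are ReLU and the output
is a sigmoid.  Training minimizes binary cross-entropy with the Adam
optimizer, with early stopping on a held-out validation split.

The network is implemented directly on NumPy arrays: the model is tiny
(tens of thousands of parameters, single input channel), so explicit
im2col convolutions with hand-derived gradients are fast, dependency-free
and bit-reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class CnnConfig:
    """Architecture + optimization settings of the temporal smoother."""

    lookback: int = 30
    filters: tuple[int, int, int] = (32, 64, 64)
    kernels: tuple[int, int, int] = (5, 5, 3)
    fc: tuple[int, int] = (64, 1)
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 256
    patience: int = 5
    min_delta: float = 1e-4
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.filters) != 3 or len(self.kernels) != 3:
            raise ValueError("exactly 3 convolution layers are required")
        if len(self.fc) != 2 or self.fc[1] != 1:
            raise ValueError("exactly 2 fully connected layers ending in one unit")
        # length after conv(k1) -> pool2 -> conv(k2) -> pool2 -> conv(k3)
        l1 = (self.lookback - self.kernels[0] + 1) // 2
        l2 = (l1 - self.kernels[1] + 1) // 2
        l3 = l2 - self.kernels[2] + 1
        if l3 < 1:
            raise ValueError("lookback too short for the kernel/pooling stack")


def _conv_forward(x, W, b):
    # x (N,C,L), W (F,C,k) -> out (N,F,Lo) via one GEMM on im2col patches
    F, C, k = W.shape
    win = sliding_window_view(x, k, axis=2)          # (N,C,Lo,k)
    Lo = win.shape[2]
    cols = win.transpose(0, 2, 1, 3).reshape(-1, C * k)      # (N*Lo, C*k)
    out = cols @ W.reshape(F, C * k).T                        # (N*Lo, F)
    out = out.reshape(x.shape[0], Lo, F).transpose(0, 2, 1) + b[None, :, None]
    return out, cols


def _conv_backward(dout, cols, W, x_shape):
    F, C, k = W.shape
    N, _, Lo = dout.shape
    dflat = dout.transpose(0, 2, 1).reshape(-1, F)            # (N*Lo, F)
    dW = (dflat.T @ cols).reshape(F, C, k)
    db = dflat.sum(axis=0)
    dcols = dflat @ W.reshape(F, C * k)                       # (N*Lo, C*k)
    dwin = dcols.reshape(N, Lo, C, k)
    dx = np.zeros(x_shape)
    for j in range(k):  # scatter the k taps back onto the input
        dx[:, :, j:j + Lo] += dwin[:, :, :, j].transpose(0, 2, 1)
    return dx, dW, db


def _maxpool2(x):
    L = x.shape[2] - (x.shape[2] % 2)
    xr = x[:, :, :L].reshape(x.shape[0], x.shape[1], L // 2, 2)
    arg = xr.argmax(axis=3)
    return xr.max(axis=3), (arg, L, x.shape)


def _maxpool2_backward(dout, cache):
    arg, L, shape = cache
    dx = np.zeros(shape)
    n, f, p = np.indices(arg.shape)
    dx[:, :, :L].reshape(shape[0], shape[1], L // 2, 2)[n, f, p, arg] = dout
    return dx


class Stage2Model:
    """Trained temporal smoother (parameters + config)."""

    def __init__(self, params: dict, config: CnnConfig):
        self.params = params
        self.config = config

    # ------------------------------------------------------------ forward

    def _forward(self, X, train=False):
        p = self.params
        x = X[:, None, :]  # single channel
        caches = []
        h = x
        for i in range(3):
            z, win = _conv_forward(h, p[f"W{i}"], p[f"b{i}"])
            a = np.maximum(z, 0.0)
            if i < 2:
                pooled, pc = _maxpool2(a)
                caches.append((h.shape, win, z, pc))
                h = pooled
            else:
                caches.append((h.shape, win, z, None))
                h = a.mean(axis=2)  # global average pooling -> (N, F3)
        z4 = h @ p["W3"] + p["b3"]
        a4 = np.maximum(z4, 0.0)
        z5 = (a4 @ p["W4"] + p["b4"]).ravel()
        if not train:
            return z5
        return z5, (caches, h, z4, a4)

    def predict_logits(self, X):
        return self._forward(np.asarray(X, dtype=float))

    def predict(self, X):
        return 1.0 / (1.0 + np.exp(-self.predict_logits(X)))

    # ----------------------------------------------------------- backward

    def _backward(self, X, y, cache):
        p = self.params
        n = len(y)
        z5, (caches, gap, z4, a4) = cache
        prob = 1.0 / (1.0 + np.exp(-z5))
        dz5 = (prob - y) / n                               # BCE-with-logits
        grads = {}
        grads["W4"] = a4.T @ dz5[:, None]
        grads["b4"] = np.array([dz5.sum()])
        da4 = dz5[:, None] @ p["W4"].T
        dz4 = da4 * (z4 > 0)
        grads["W3"] = gap.T @ dz4
        grads["b3"] = dz4.sum(axis=0)
        dgap = dz4 @ p["W3"].T                             # (N, F3)
        # back through GAP of conv3
        h_shape, win, z, _ = caches[2]
        L3 = z.shape[2]
        da = np.repeat(dgap[:, :, None] / L3, L3, axis=2)
        dz = da * (z > 0)
        dh, grads["W2"], grads["b2"] = _conv_backward(dz, win, p["W2"], h_shape)
        for i in (1, 0):
            h_shape, win, z, pc = caches[i]
            da = _maxpool2_backward(dh, pc)
            dz = da * (z > 0)
            dh, grads[f"W{i}"], grads[f"b{i}"] = _conv_backward(
                dz, win, p[f"W{i}"], h_shape)
        return grads

    # --------------------------------------------------------------- io

    def save(self, path) -> None:
        """Single portable .npz with the config embedded."""
        arrays = {k: v for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.__dict__, default=list).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Stage2Model":
        data = np.load(path)
        raw = json.loads(bytes(data["__config__"]).decode())
        for key in ("filters", "kernels", "fc"):
            raw[key] = tuple(raw[key])
        cfg = CnnConfig(**raw)
        params = {k: data[k] for k in data.files if k != "__config__"}
        return cls(params, cfg)

    def layer_summary(self) -> list[str]:
        """Structural description: one line per layer."""
        c = self.config
        lines = [f"conv1d(filters={c.filters[0]}, kernel={c.kernels[0]}) + relu + maxpool2",
                 f"conv1d(filters={c.filters[1]}, kernel={c.kernels[1]}) + relu + maxpool2",
                 f"conv1d(filters={c.filters[2]}, kernel={c.kernels[2]}) + relu + global_avg_pool",
                 f"fc({c.fc[0]}) + relu",
                 "fc(1) + sigmoid"]
        return lines


def _init_params(cfg: CnnConfig, rng: np.random.Generator) -> dict:
    f = (1,) + tuple(cfg.filters)
    params = {}
    for i in range(3):
        fan_in = f[i] * cfg.kernels[i]
        params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                     size=(f[i + 1], f[i], cfg.kernels[i]))
        params[f"b{i}"] = np.zeros(f[i + 1])
    params["W3"] = rng.normal(0, np.sqrt(2.0 / cfg.filters[2]),
                              size=(cfg.filters[2], cfg.fc[0]))
    params["b3"] = np.zeros(cfg.fc[0])
    params["W4"] = rng.normal(0, np.sqrt(2.0 / cfg.fc[0]), size=(cfg.fc[0], 1))
    params["b4"] = np.zeros(1)
    return params


def make_sequences(provisional_by_day, labels_by_day, L: int):
    """Training pairs from aligned per-day minute series.

    For each day and each minute t with at least L preceding minutes within
    the day, the input is ``provisional[t-L:t]`` and the target the GPS
    label at t.  Sequences never cross day boundaries.
    Returns (X (N, L), y (N,), groups (N,)) where groups indexes the source
    day of each pair — consecutive windows overlap in L-1 minutes, so any
    train/validation split must respect day boundaries.
    """
    xs, ys, gs = [], [], []
    for day_idx, (prov, lab) in enumerate(zip(provisional_by_day, labels_by_day)):
        prov = np.asarray(prov, dtype=float)
        lab = np.asarray(lab)
        if L > len(prov):
            raise ValueError("lookback exceeds the day span")
        if L == len(prov):
            continue  # zero pairs for this day
        win = sliding_window_view(prov, L)[:-1]  # windows ending before t
        xs.append(win)
        ys.append(lab[L:])
        gs.append(np.full(len(win), day_idx))
    if not xs:
        return np.empty((0, L)), np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.vstack(xs), np.concatenate(ys).astype(int), np.concatenate(gs)


def train_stage2(X, y, config: CnnConfig | None = None, groups=None) -> Stage2Model:
    """Fit the smoother on (N, L) sequence inputs with binary targets.

    ``groups`` (day index per pair, as returned by :func:`make_sequences`)
    makes the early-stopping validation split day-blocked: neighboring
    sequence windows share L-1 of their L minutes, so a random minute-level
    split would leak training data into the validation set and disable
    early stopping.  Without groups a random split is used.
    """
    config = config or CnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the stage-2 training set")
    if X.shape[1] != config.lookback:
        raise ValueError("sequence length does not match config.lookback")
    rng = np.random.default_rng(config.seed)
    model = Stage2Model(_init_params(config, rng), config)

    n = len(y)
    if groups is not None and len(np.unique(groups)) >= 2:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        n_val_days = max(1, int(round(config.val_fraction * len(uniq))))
        val_days = rng.choice(uniq, size=n_val_days, replace=False)
        val_mask = np.isin(groups, val_days)
        if len(np.unique(y[~val_mask])) < 2:  # degenerate split, fall back
            val_mask = np.zeros(n, dtype=bool)
            val_mask[rng.permutation(n)[:max(1, int(config.val_fraction * n))]] = True
        val_idx, tr_idx = np.flatnonzero(val_mask), np.flatnonzero(~val_mask)
    else:
        order = rng.permutation(n)
        n_val = max(1, int(round(config.val_fraction * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx = val_idx
    Xtr, ytr, Xva, yva = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_loss, best_params, wait = np.inf, None, 0

    def val_loss():
        z = model._forward(Xva)
        return float(np.mean(np.logaddexp(0.0, z) - yva * z))

    for _ in range(config.epochs):
        perm = rng.permutation(len(ytr))
        for s in range(0, len(ytr), config.batch_size):
            idx = perm[s:s + config.batch_size]
            out = model._forward(Xtr[idx], train=True)
            grads = model._backward(Xtr[idx], ytr[idx], out)
            t += 1
            for k2, g in grads.items():
                m[k2] = beta1 * m[k2] + (1 - beta1) * g
                v[k2] = beta2 * v[k2] + (1 - beta2) * g * g
                mh = m[k2] / (1 - beta1 ** t)
                vh = v[k2] / (1 - beta2 ** t)
                model.params[k2] = model.params[k2] - config.lr * mh / (np.sqrt(vh) + eps)
        loss = val_loss()
        if loss < best_loss - config.min_delta:
            best_loss, wait = loss, 0
            best_params = {k2: p.copy() for k2, p in model.params.items()}
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def predict_series(model: Stage2Model, provisional: np.ndarray) -> np.ndarray:
    """Final per-minute probabilities for one day's provisional series.

    The first ``lookback`` minutes have no full history and pass the
    provisional value through unchanged (warm-up rule); the rest are the
    smoother's sigmoid outputs.  Deterministic.
    """
    prov = np.asarray(provisional, dtype=float)
    L = model.config.lookback
    if len(prov) < L:
        raise ValueError("series shorter than the lookback")
    out = prov.copy()
    if len(prov) == L:
        return out
    win = sliding_window_view(prov, L)[:-1]
    out[L:] = model.predict(win)
    return out
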