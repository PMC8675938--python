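"""A 1-D convolutional network for per-cycle CAD probability.

Architecture (input: one 750-sample intensity vector):

* block 1 — conv(32 filters, kernel 10, same padding), ReLU, batch
  normalisation (placed after the activation), max-pool 2;
* blocks 2 and 3 — conv(16 filters, kernel 10, same), ReLU, max-pool
  2, dropout (default rate 0.25);
* two fully connected layers of 1,000 units, each with ReLU and
  dropout 0.5;
* a 2-unit softmax head (CAD is class 1).

Training uses Adam on cross-entropy for a fixed number of epochs,
records validation accuracy after every epoch, and keeps the weights
of the epoch with the highest validation accuracy (earliest on ties).

The implementation is plain numpy: convolutions are im2col + GEMM in
float32, and every source of randomness (init, shuffling, dropout)
derives from one integer seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ModelStateError, ShapeError, TrainingError, ValidationError

_F32 = np.float32


@dataclass
class CnnSpec:
    """Hyperparameters of the channel classifier."""

    input_len: int = 750
    n_filters: Tuple[int, int, int] = (32, 16, 16)
    kernel_size: int = 10
    pool_size: int = 2
    conv_dropout: float = 0.25
    fc_units: int = 1000
    fc_dropout: float = 0.5
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 128

    def __post_init__(self):
        if self.input_len <= 0 or self.kernel_size <= 0:
            raise ValidationError("input_len and kernel_size must be positive")
        if not 0 <= self.conv_dropout < 1 or not 0 <= self.fc_dropout < 1:
            raise ValidationError("dropout rates must lie in [0, 1)")

    @property
    def flat_len(self) -> int:
        n = self.input_len
        for _ in self.n_filters:
            n //= self.pool_size
        return n * self.n_filters[-1]


class _Conv:
    """'Same'-padded 1-D convolution over a (B, L, C) batch.

    Weights are stored as (k, C_in, C_out).  The padded batch is
    viewed as one long (B*Lp, C) matrix; windows that straddle sample
    boundaries only ever land in pad margins, which the final slice
    discards.  Two equivalent evaluation strategies are chosen by
    memory traffic: an explicit im2col buffer with a single GEMM when
    the input is narrow (C*k small), or k shifted full-width GEMMs
    accumulated in place when the output is narrower.  ``needs_dx``
    is False for the first layer, whose input gradient nobody uses.
    """

    def __init__(self, c_in, c_out, k, rng, needs_dx=True):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((k, c_in, c_out)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k, self.c_in = k, c_in
        self.needs_dx = needs_dx
        self._im2col = c_in * k <= k * c_out

    def forward(self, x, train):
        b, l, c = x.shape
        k = self.k
        pl = (k - 1) // 2
        lp = l + k - 1
        xp = np.pad(x, ((0, 0), (pl, k - 1 - pl), (0, 0)))
        flat = xp.reshape(b * lp, c)
        m = b * lp - k + 1
        f = self.W.shape[2]
        cols = None
        if self._im2col:
            cols = np.empty((m, c * k), dtype=_F32)
            for j in range(k):
                cols[:, j * c : (j + 1) * c] = flat[j : j + m]
            acc = cols @ self.W.reshape(k * c, f)
        else:
            acc = flat[0:m] @ self.W[0]
            tmp = np.empty_like(acc)
            for j in range(1, k):
                np.matmul(flat[j : j + m], self.W[j], out=tmp)
                acc += tmp
        out_full = np.empty((b * lp, f), dtype=_F32)
        out_full[:m] = acc
        out = np.ascontiguousarray(out_full.reshape(b, lp, f)[:, :l, :])
        out += self.b
        self._cache = (flat, cols, b, l) if train else None
        return out

    def backward(self, dout):
        flat, cols, b, l = self._cache
        k, c = self.k, self.c_in
        f = dout.shape[2]
        lp = l + k - 1
        m = b * lp - k + 1
        dlong = np.zeros((b * lp, f), dtype=_F32)
        dlong.reshape(b, lp, f)[:, :l, :] = dout
        dlong = dlong[:m]
        if cols is not None:
            self.dW = (cols.T @ dlong).reshape(k, c, f)
        else:
            self.dW = np.empty_like(self.W)
            for j in range(k):
                self.dW[j] = flat[j : j + m].T @ dlong
        self.db = dout.sum(axis=(0, 1))
        if not self.needs_dx:
            return None
        dflat = np.zeros((b * lp, c), dtype=_F32)
        for j in range(k):
            dflat[j : j + m] += dlong @ self.W[j].T
        pl = (k - 1) // 2
        return np.ascontiguousarray(dflat.reshape(b, lp, c)[:, pl : pl + l, :])


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.run_mean = np.zeros(c, dtype=_F32)
        self.run_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(_F32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        # single-pass affine: x * (gamma*inv) + (beta - mean*gamma*inv)
        scale = self.gamma * inv
        if train:
            self._cache = (x, mean.astype(_F32), inv, x.shape[0] * x.shape[1])
        return x * scale + (self.beta - mean * scale)

    def backward(self, dout):
        # dx = (gamma*inv/m) * (m*dout - dbeta - xhat*dgamma), computed
        # in place: the cached activation buffer is consumed as scratch.
        x, mean, inv, m = self._cache
        self._cache = None
        xhat = x
        xhat -= mean
        xhat *= inv
        self.dgamma = np.einsum("blc,blc->c", dout, xhat, optimize=False).astype(_F32)
        self.dbeta = dout.sum(axis=(0, 1))
        xhat *= self.dgamma * _F32(1.0 / m)
        dx = dout if dout.flags.writeable else dout.copy()
        dx -= self.dbeta * _F32(1.0 / m)
        dx -= xhat
        dx *= self.gamma * inv
        return dx


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)

    def forward(self, x, train):
        if train:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dout):
        x = self._cache
        self.dW = x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


def _maxpool(x, p):
    b, l, c = x.shape
    lt = (l // p) * p
    if p != 2:
        xv = x[:, :lt].reshape(b, l // p, p, c)
        idx = xv.argmax(axis=2)
        return xv.max(axis=2), (idx, x.shape, lt)
    a, bb = x[:, 0:lt:2, :], x[:, 1:lt:2, :]
    mask = a >= bb
    return np.where(mask, a, bb), (mask, x.shape, lt)


def _maxpool_back(dout, cache, p):
    sel, shape, lt = cache
    b, lp, c = dout.shape
    dx = np.zeros(shape, dtype=_F32)
    if p != 2:
        dxv = dx[:, :lt].reshape(b, lp, p, c)
        np.put_along_axis(dxv, sel[:, :, None, :], dout[:, :, None, :], axis=2)
        dx[:, :lt] = dxv.reshape(b, lt, c)
        return dx
    dx[:, 0:lt:2, :] = np.where(sel, dout, 0.0)
    dx[:, 1:lt:2, :] = np.where(sel, 0.0, dout)
    return dx


class Cnn1d:
    """The network itself; see the module docstring for the layout."""

    def __init__(self, spec: CnnSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        f1, f2, f3 = spec.n_filters
        k = spec.kernel_size
        self.conv1 = _Conv(1, f1, k, rng, needs_dx=False)
        self.bn1 = _BatchNorm(f1)
        self.conv2 = _Conv(f1, f2, k, rng)
        self.conv3 = _Conv(f2, f3, k, rng)
        self.fc1 = _Dense(spec.flat_len, spec.fc_units, rng)
        self.fc2 = _Dense(spec.fc_units, spec.fc_units, rng)
        self.head = _Dense(spec.fc_units, spec.n_classes, rng)
        self._drop_rng = np.random.default_rng(seed + 1)
        self._layers = [self.conv1, self.bn1, self.conv2, self.conv3,
                        self.fc1, self.fc2, self.head]

    # -- forward / backward ---------------------------------------------

    def _dropout(self, x, rate, train):
        if not train or rate == 0:
            return x, None
        mask = (self._drop_rng.random(x.shape) >= rate).astype(_F32) / (1 - rate)
        return x * mask, mask

    def forward(self, x: np.ndarray, train: bool = False):
        spec = self.spec
        if x.ndim != 2 or x.shape[1] != spec.input_len:
            raise ShapeError(
                f"expected input of shape (batch, {spec.input_len}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=_F32)[:, :, None]  # (B, L, 1)
        cache = {}
        # block 1: conv -> ReLU -> BN -> pool
        a = self.conv1.forward(x, train)
        r1 = a > 0
        np.maximum(a, 0.0, out=a)
        a = self.bn1.forward(a, train)
        a, cache["p1"] = _maxpool(a, spec.pool_size)
        # block 2: conv -> ReLU -> pool -> dropout
        a2 = self.conv2.forward(a, train)
        r2 = a2 > 0
        np.maximum(a2, 0.0, out=a2)
        a2, cache["p2"] = _maxpool(a2, spec.pool_size)
        a2, cache["d2"] = self._dropout(a2, spec.conv_dropout, train)
        # block 3
        a3 = self.conv3.forward(a2, train)
        r3 = a3 > 0
        np.maximum(a3, 0.0, out=a3)
        a3, cache["p3"] = _maxpool(a3, spec.pool_size)
        a3, cache["d3"] = self._dropout(a3, spec.conv_dropout, train)
        flat = a3.reshape(x.shape[0], -1)
        # FC stack
        h1 = self.fc1.forward(flat, train)
        rh1 = h1 > 0
        np.maximum(h1, 0.0, out=h1)
        h1, cache["d4"] = self._dropout(h1, spec.fc_dropout, train)
        h2 = self.fc2.forward(h1, train)
        rh2 = h2 > 0
        np.maximum(h2, 0.0, out=h2)
        h2, cache["d5"] = self._dropout(h2, spec.fc_dropout, train)
        logits = self.head.forward(h2, train)
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        if train:
            cache.update(r1=r1, r2=r2, r3=r3, rh1=rh1, rh2=rh2,
                         flat_shape=a3.shape)
            self._cache = cache
        return probs

    def backward(self, probs, y_onehot):
        c = self._cache
        spec = self.spec
        b = probs.shape[0]
        dlogits = ((probs - y_onehot) / b).astype(_F32)
        d = self.head.backward(dlogits)
        if c["d5"] is not None:
            d = d * c["d5"]
        d = self.fc2.backward(d * c["rh2"])
        if c["d4"] is not None:
            d = d * c["d4"]
        d = self.fc1.backward(d * c["rh1"])
        d = d.reshape(c["flat_shape"])
        if c["d3"] is not None:
            d = d * c["d3"]
        d = _maxpool_back(d, c["p3"], spec.pool_size)
        d = self.conv3.backward(d * c["r3"])
        if c["d2"] is not None:
            d = d * c["d2"]
        d = _maxpool_back(d, c["p2"], spec.pool_size)
        d = self.conv2.backward(d * c["r2"])
        d = _maxpool_back(d, c["p1"], spec.pool_size)
        d = self.bn1.backward(d)
        self.conv1.backward(d * c["r1"])

    # -- parameters ------------------------------------------------------

    def _param_items(self):
        return [
            ("conv1.W", self.conv1, "W"), ("conv1.b", self.conv1, "b"),
            ("bn1.gamma", self.bn1, "gamma"), ("bn1.beta", self.bn1, "beta"),
            ("conv2.W", self.conv2, "W"), ("conv2.b", self.conv2, "b"),
            ("conv3.W", self.conv3, "W"), ("conv3.b", self.conv3, "b"),
            ("fc1.W", self.fc1, "W"), ("fc1.b", self.fc1, "b"),
            ("fc2.W", self.fc2, "W"), ("fc2.b", self.fc2, "b"),
            ("head.W", self.head, "W"), ("head.b", self.head, "b"),
        ]

    def get_weights(self) -> Dict[str, np.ndarray]:
        w = {name: getattr(obj, attr).copy() for name, obj, attr in self._param_items()}
        w["bn1.run_mean"] = self.bn1.run_mean.copy()
        w["bn1.run_var"] = self.bn1.run_var.copy()
        return w

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for name, obj, attr in self._param_items():
            setattr(obj, attr, weights[name].astype(_F32).copy())
        self.bn1.run_mean = weights["bn1.run_mean"].astype(_F32).copy()
        self.bn1.run_var = weights["bn1.run_var"].astype(_F32).copy()


class _Adam:
    def __init__(self, net: Cnn1d, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(getattr(o, a)) for n, o, a in net._param_items()}
        self.v = {n: np.zeros_like(getattr(o, a)) for n, o, a in net._param_items()}

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        step_scale = _F32(self.lr * np.sqrt(b2t) / b1t)
        eps = _F32(self.eps * np.sqrt(b2t))
        for name, obj, attr in self.net._param_items():
            grad = getattr(obj, "d" + attr).astype(_F32, copy=False)
            m, v = self.m[name], self.v[name]
            m *= _F32(self.b1)
            m += _F32(1 - self.b1) * grad
            v *= _F32(self.b2)
            np.square(grad, out=grad)
            grad *= _F32(1 - self.b2)
            v += grad
            denom = np.sqrt(v)
            denom += eps
            w = getattr(obj, attr)
            w -= step_scale * m / denom


@dataclass
class ChannelClassifier:
    """A (possibly trained) classifier for one SCG/GCG channel."""

    channel: str
    spec: CnnSpec
    seed: int
    weights: Optional[Dict[str, np.ndarray]] = None
    history: Dict[str, List[float]] = field(default_factory=dict)
    selected_epoch: Optional[int] = None

    @property
    def is_trained(self) -> bool:
        return self.weights is not None

    def network(self) -> Cnn1d:
        net = Cnn1d(self.spec, self.seed)
        if self.weights is not None:
            net.set_weights(self.weights)
        return net

    def save(self, path) -> None:
        path = Path(path)
        if not self.is_trained:
            raise ModelStateError("cannot save an untrained classifier")
        meta = {
            "channel": self.channel,
            "seed": self.seed,
            "spec": asdict(self.spec),
            "history": self.history,
            "selected_epoch": self.selected_epoch,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.weights)

    @classmethod
    def load(cls, path) -> "ChannelClassifier":
        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}.npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            weights = {k: z[k] for k in z.files if k != "__meta__"}
        spec = CnnSpec(**{**meta["spec"], "n_filters": tuple(meta["spec"]["n_filters"])})
        return cls(
            channel=meta["channel"], spec=spec, seed=meta["seed"], weights=weights,
            history=meta["history"], selected_epoch=meta["selected_epoch"],
        )


def build_model(spec: CnnSpec, seed: int, channel: str = "") -> ChannelClassifier:
    """An untrained classifier; the seed fixes its initial weights."""
    return ChannelClassifier(channel=channel, spec=spec, seed=seed)


def _check_xy(x, y, name):
    x = np.ascontiguousarray(x, dtype=_F32)
    y = np.asarray(y, dtype=int)
    if x.shape[0] != y.size:
        raise ValidationError(f"{name}: features and labels disagree in length")
    return x, y


def train_channel(
    x_train,
    y_train,
    x_val,
    y_val,
    spec: CnnSpec = None,
    epochs: int = 100,
    seed: int = 0,
    channel: str = "",
) -> ChannelClassifier:
    """Train one channel classifier and keep the best-validation weights.

    Labels are 0 (non-CAD) / 1 (CAD).  Raises ``TrainingError`` when
    the training set contains a single class.
    """
    spec = spec or CnnSpec()
    x_train, y_train = _check_xy(x_train, y_train, "train")
    x_val, y_val = _check_xy(x_val, y_val, "validation")
    if np.unique(y_train).size < 2:
        raise TrainingError("training set contains a single class")
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")

    net = Cnn1d(spec, seed)
    opt = _Adam(net, spec.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 2)
    eye = np.eye(spec.n_classes, dtype=_F32)

    best_acc, best_weights, best_epoch = -1.0, None, None
    train_loss_hist, val_acc_hist = [], []
    n = x_train.shape[0]
    bs = min(spec.batch_size, n)
    for epoch in range(1, epochs + 1):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x_train[idx], y_train[idx]
            probs = net.forward(xb, train=True)
            p_true = np.clip(probs[np.arange(len(idx)), yb], 1e-12, None)
            losses.append(float(-np.log(p_true).mean()))
            net.backward(probs, eye[yb])
            opt.step()
        val_probs = predict_proba(net, x_val)
        acc = float(((val_probs[:, 1] >= 0.5).astype(int) == y_val).mean())
        train_loss_hist.append(float(np.mean(losses)))
        val_acc_hist.append(acc)
        if acc > best_acc:  # strict: earliest epoch wins ties
            best_acc, best_epoch = acc, epoch
            best_weights = net.get_weights()

    return ChannelClassifier(
        channel=channel,
        spec=spec,
        seed=seed,
        weights=best_weights,
        history={"train_loss": train_loss_hist, "val_accuracy": val_acc_hist},
        selected_epoch=best_epoch,
    )


def predict_proba(net: Cnn1d, x: np.ndarray, batch: int = 256) -> np.ndarray:
    """Eval-mode class probabilities, computed in batches."""
    x = np.ascontiguousarray(x, dtype=_F32)
    return np.concatenate(
        [net.forward(x[i : i + batch], train=False) for i in range(0, len(x), batch)]
    )


def predict_cycles(model: ChannelClassifier, features) -> np.ndarray:
    """Per-cycle CAD probability (softmax component of class 1)."""
    if not model.is_trained:
        raise ModelStateError("classifier has not been trained")
    if hasattr(features, "__len__") and len(features) and hasattr(features[0], "values"):
        x = np.stack([f.values for f in features])
    else:
        x = np.asarray(features, dtype=float)
    return predict_proba(model.network(), x)[:, 1]
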