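"""A small numpy CNN engine executing linear :class:`~dedscreen.models.CnnSpec`s.

Supports the layer kinds used by the screening CNN — same-padding 5x5
convolutions (stride 1), 2x2 max pooling, ReLU, flatten, inverted dropout,
dense layers, and a sigmoid or softmax head — with reverse-mode gradients
and RMSprop / Adam optimizers.  It is single-threaded, float32, and
deterministic given a seed, which is exactly what reproducible CPU-scale
experiments need.

Binary heads are trained with binary cross-entropy on logits; multiclass
heads with categorical cross-entropy on logits.
"""

from __future__ import annotations

import numpy as np

from dedscreen.models import CnnSpec, LayerSpec


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv:
    """Same-padding stride-1 convolution via sliding windows + tensordot."""

    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        kh, kw, cin = spec.kernel
        self.kh, self.kw = kh, kw
        self.w = _he_init(rng, (kh, kw, cin, spec.filters), kh * kw * cin)
        self.b = np.zeros(spec.filters, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # win: (N, H, W, C, kh, kw); kernel: (kh, kw, C, F)
        self._win_shape = xp.shape
        self._x = x
        out = np.tensordot(win, self.w, axes=([4, 5, 3], [0, 1, 2])) + self.b
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # dW[kh,kw,C,F] = sum_{N,H,W} win[N,H,W,C,kh,kw] * dout[N,H,W,F]
        self.dw = np.tensordot(win, dout, axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3)
        self.db = dout.sum(axis=(0, 1, 2))
        # dx: full correlation of dout with the spatially flipped kernel.
        dp = np.pad(dout, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        dwin = np.lib.stride_tricks.sliding_window_view(dp, (self.kh, self.kw), axis=(1, 2))
        w_flip = self.w[::-1, ::-1]  # (kh, kw, C, F)
        dx = np.tensordot(dwin, w_flip, axes=([4, 5, 3], [0, 1, 3]))
        self.grads = [("w", self.dw), ("b", self.db)]
        return dx.astype(np.float32)


class _MaxPool:
    def __init__(self, spec: LayerSpec):
        self.sh, self.sw = spec.stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // self.sh, w // self.sw
        xr = x[:, : h2 * self.sh, : w2 * self.sw].reshape(n, h2, self.sh, w2, self.sw, c)
        out = xr.max(axis=(2, 4))
        self._x_shape = x.shape
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        dxr = self._mask * (dout[:, :, None, :, None, :] / counts)
        return dxr.reshape(n, h, w, c).astype(np.float32)


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dropout:
    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        self.rate = spec.rate or 0.0
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class _Dense:
    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        fan_in = spec.kernel[2]
        self.w = _he_init(rng, (fan_in, spec.units), fan_in)
        self.b = np.zeros(spec.units, dtype=np.float32)
        self.activation = spec.activation
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        self._mask = None
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is not None:
            dout = dout * self._mask
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self.grads = [("w", self.dw), ("b", self.db)]
        return (dout @ self.w.T).astype(np.float32)


_OPTIMIZERS = ("rmsprop", "adam")


class NumpyCnn:
    """Compile a linear CnnSpec into trainable numpy layers.

    The output layer produces logits; :meth:`predict_proba` applies the
    head activation (sigmoid or softmax).
    """

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.layers: list = []
        for ls in spec.layers:
            if ls.kind == "conv":
                if ls.stride != (1, 1) or ls.padding != "same":
                    raise ValueError("engine supports stride-1 same-padding conv only")
                self.layers.append(_Conv(ls, self.rng))
            elif ls.kind == "maxpool":
                self.layers.append(_MaxPool(ls))
            elif ls.kind == "relu":
                self.layers.append(_ReLU())
            elif ls.kind == "flatten":
                self.layers.append(_Flatten())
            elif ls.kind == "dropout":
                self.layers.append(_Dropout(ls, self.rng))
            elif ls.kind in ("dense", "output"):
                self.layers.append(_Dense(ls, self.rng))
            else:
                raise ValueError(f"engine cannot execute layer kind {ls.kind!r}")
        self.head_activation = spec.layers[-1].activation
        self._opt_state: dict = {}
        self._step = 0

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                return_layer_outputs: bool = False):
        out = x.astype(np.float32)
        outputs = []
        for layer in self.layers:
            out = layer.forward(out, train)
            if return_layer_outputs:
                outputs.append(out)
        return (out, outputs) if return_layer_outputs else out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            if self.head_activation == "softmax":
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs.append(e / e.sum(axis=1, keepdims=True))
            else:
                probs.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        if self.head_activation == "softmax":
            return p.argmax(axis=1)
        return (p[:, 0] >= 0.5).astype(np.int64)

    # -- training ----------------------------------------------------------

    def _loss_and_dlogits(self, logits: np.ndarray, y: np.ndarray):
        n = len(y)
        if self.head_activation == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss = -log_probs[np.arange(n), y].mean()
            probs = np.exp(log_probs)
            probs[np.arange(n), y] -= 1.0
            return float(loss), (probs / n).astype(np.float32)
        yf = y.astype(np.float32).reshape(-1, 1)
        z = logits
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.maximum(z, 0) - z * yf + np.log1p(np.exp(-np.abs(z)))))
        p = 1.0 / (1.0 + np.exp(-z))
        return loss, ((p - yf) / n).astype(np.float32)

    def _update(self, optimizer: str, lr: float) -> None:
        self._step += 1
        for li, layer in enumerate(self.layers):
            if not hasattr(layer, "grads"):
                continue
            for (pname, p), (_, g) in zip(layer.params, layer.grads):
                key = (li, pname)
                if optimizer == "rmsprop":
                    state = self._opt_state.setdefault(key, np.zeros_like(p))
                    state *= 0.9
                    state += 0.1 * g * g
                    p -= lr * g / (np.sqrt(state) + 1e-7)
                elif optimizer == "adam":
                    m, v = self._opt_state.setdefault(
                        key, (np.zeros_like(p), np.zeros_like(p)))
                    m *= 0.9
                    m += 0.1 * g
                    v *= 0.999
                    v += 0.001 * g * g
                    mhat = m / (1 - 0.9**self._step)
                    vhat = v / (1 - 0.999**self._step)
                    p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                else:
                    raise ValueError(f"unknown optimizer {optimizer!r}; "
                                     f"choose from {_OPTIMIZERS}")

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        optimizer: str = "rmsprop",
        lr: float = 3e-4,
        shuffle_seed: int = 0,
    ) -> list[dict]:
        """Mini-batch training; returns one history record per epoch."""
        if optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {optimizer!r}")
        x = x.astype(np.float32)
        y = np.asarray(y)
        order_rng = np.random.default_rng(shuffle_seed)
        history: list[dict] = []
        for _ in range(epochs):
            idx = order_rng.permutation(len(x))
            losses = []
            correct = 0
            for i in range(0, len(x), batch_size):
                sel = idx[i : i + batch_size]
                logits = self.forward(x[sel], train=True)
                loss, dlogits = self._loss_and_dlogits(logits, y[sel])
                losses.append(loss * len(sel))
                if self.head_activation == "softmax":
                    correct += int((logits.argmax(axis=1) == y[sel]).sum())
                else:
                    correct += int(((logits[:, 0] >= 0) == (y[sel] == 1)).sum())
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                self._update(optimizer, lr)
            history.append({
                "loss": float(np.sum(losses) / len(x)),
                "accuracy": correct / len(x),
            })
        return history
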