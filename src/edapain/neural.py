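"""Compact feed-forward and 1D-convolutional classifiers in plain numpy.

Both architectures mirror the shapes used for window-level EDA classification:

* MLP: flatten -> dropout + dense(250, ReLU) -> dropout + dense(100, ReLU)
  -> dense(2) + softmax.
* CNN: three blocks of (same-padded temporal convolution, ReLU, max pooling,
  dropout) with 32/64/128 filters, kernel 16 and pool 8, then flatten ->
  dense(2) + softmax.

Training minimises softmax cross-entropy with Adam (batch 32, learning rate
1e-4 by default) and is bit-reproducible for a fixed seed. Backpropagation is
written out layer by layer, which doubles as the gradient machinery for
Grad-CAM: the model can return the last convolutional feature maps together
with the gradient of any pre-softmax class score with respect to them, and
can re-run the head from a perturbed feature map (used by finite-difference
checks).

Windows enter as (time, 1) arrays after the resample/normalise/smooth
pipeline; every parameter here is a plain numpy array, so checkpoints are
ordinary ``.npz`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DenseNeuronSpec",
    "dense_forward",
    "TrainConfig",
    "Model",
    "build_mlp",
    "build_cnn",
    "train_classifier",
    "predict_proba",
    "predict_label_indices",
    "penultimate_features",
]


# ---------------------------------------------------------------------------
# single neuron (executable definition of the dense unit)

@dataclass(frozen=True)
class DenseNeuronSpec:
    """One artificial neuron: y = sigma(b + sum_k w_k x_k)."""

    weights: np.ndarray
    bias: float
    activation: str = "identity"  # identity | relu


def dense_forward(spec: DenseNeuronSpec, inputs: np.ndarray) -> float:
    w = np.asarray(spec.weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if w.shape != x.shape:
        raise ValueError("input length must equal the neuron fan-in")
    y = spec.bias + float(w @ x)
    if spec.activation == "relu":
        return max(y, 0.0)
    if spec.activation == "identity":
        return y
    raise ValueError(f"unknown activation {spec.activation!r}")


# ---------------------------------------------------------------------------
# layers

class Layer:
    params: tuple = ()

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None
                ) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def grads(self) -> tuple:
        return ()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if train and self.rate > 0:
            self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1D(Layer):
    """Same-padded temporal convolution on (batch, time, channels) arrays."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = rng.normal(0.0, scale, size=(kernel * c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def forward(self, x, train, rng):
        n, l, _ = x.shape
        k = self.kernel
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        # (n, l, c_in, k) -> (n, l, k, c_in) -> (n*l, k*c_in)
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = cols.transpose(0, 1, 3, 2).reshape(n * l, k * self.c_in)
        self._cols = cols
        self._in_shape = (n, l, pad_l)
        return (cols @ self.W + self.b).reshape(n, l, self.c_out)

    def backward(self, dout):
        n, l, pad_l = self._in_shape
        k = self.kernel
        d2 = dout.reshape(n * l, self.c_out)
        self.dW = self._cols.T @ d2
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(n, l, k, self.c_in)
        lp = l + k - 1
        dxp = np.zeros((n, lp, self.c_in))
        for j in range(k):
            dxp[:, j:j + l, :] += dcols[:, :, j, :]
        return dxp[:, pad_l:pad_l + l, :]


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder is dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train, rng):
        n, l, c = x.shape
        p = self.pool
        lo = l // p
        if lo < 1:
            raise ValueError(f"time axis {l} shorter than pool size {p}")
        xt = x[:, :lo * p, :].reshape(n, lo, p, c)
        self._arg = xt.argmax(axis=2)
        self._in_shape = (n, l, c)
        return xt.max(axis=2)

    def backward(self, dout):
        n, l, c = self._in_shape
        p = self.pool
        lo = l // p
        dxt = np.zeros((n, lo, p, c))
        np.put_along_axis(dxt, self._arg[:, :, None, :], dout[:, :, None, :],
                          axis=2)
        dx = np.zeros((n, l, c))
        dx[:, :lo * p, :] = dxt.reshape(n, lo * p, c)
        return dx


# ---------------------------------------------------------------------------
# model container

@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be "
                             "positive")


class Model:
    """A plain sequential network over (batch, time, channels) inputs.

    ``conv_hook`` is the layer index whose *output* is the last convolutional
    feature map (after ReLU), or None for dense-only models.
    """

    def __init__(self, layers: list[Layer], input_len: int,
                 conv_hook: int | None = None,
                 penultimate_hook: int | None = None):
        self.layers = layers
        self.input_len = input_len
        self.conv_hook = conv_hook
        self.penultimate_hook = penultimate_hook
        self.trained = False

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def _forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Eval-mode forward keeping each layer's output (index-aligned)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, False, None)
            outs.append(x)
        return outs

    def backward(self, dlogits: np.ndarray, stop_after: int = 0) -> np.ndarray:
        """Backpropagate from the logits; returns the gradient flowing out of
        layer ``stop_after`` (i.e. w.r.t. that layer's output when called with
        stop_after = hook + 1)."""
        d = dlogits
        for layer in reversed(self.layers[stop_after:]):
            d = layer.backward(d)
        return d

    def forward_from(self, layer_idx: int, activation: np.ndarray) -> np.ndarray:
        """Run the tail of the network on a substituted activation: the input
        is taken as the output of layer ``layer_idx``."""
        x = activation
        for layer in self.layers[layer_idx + 1:]:
            x = layer.forward(x, False, None)
        return x

    def class_score_gradient(self, x: np.ndarray, class_idx: int
                             ) -> tuple[np.ndarray, np.ndarray]:
        """Last-conv feature maps and d(pre-softmax y^c)/d(feature maps).

        Both arrays have shape (batch, time', channels).
        """
        if self.conv_hook is None:
            raise ValueError("model has no convolutional layer")
        outs = self._forward_collect(x)
        logits = outs[-1]
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        grad = self.backward(dlogits, stop_after=self.conv_hook + 1)
        return outs[self.conv_hook], grad

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            cfg: TrainConfig = TrainConfig()) -> list[float]:
        """Minimise softmax cross-entropy with Adam; returns per-epoch loss."""
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(cfg.seed)
        opt = _Adam(self.layers, cfg.learning_rate)
        history = []
        n = x.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self.forward(x[idx], train=True, rng=rng)
                probs = _softmax(logits)
                m = idx.size
                loss = -np.mean(np.log(probs[np.arange(m), y[idx]] + 1e-12))
                dlogits = probs.copy()
                dlogits[np.arange(m), y[idx]] -= 1.0
                dlogits /= m
                self.backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.trained = True
        return history

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_param{j}"] = p
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"layer{i}_param{j}"]
        self.trained = True


class _Adam:
    def __init__(self, layers: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# architectures

def build_mlp(input_len: int, dropout: float = 0.2, seed: int = 0) -> Model:
    """Flatten -> 2x (dropout + dense ReLU, widths 250 and 100) -> dense(2)."""
    if input_len < 1:
        raise ValueError("input_len must be >= 1")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Flatten(),
        Dropout(dropout), Dense(input_len, 250, rng), ReLU(),
        Dropout(dropout), Dense(250, 100, rng), ReLU(),
        Dense(100, 2, rng),
    ]
    return Model(layers, input_len, conv_hook=None, penultimate_hook=6)


def build_cnn(input_len: int, filters: tuple[int, int, int] = (32, 64, 128),
              kernel: int = 8, pool: int = 8, dropout: float = 0.2,
              seed: int = 0) -> Model:
    """Three conv/ReLU/maxpool/dropout blocks, then flatten -> dense(2)."""
    time = input_len
    for _ in range(3):
        time //= pool
    if time < 1:
        raise ValueError(
            f"input_len {input_len} too short for 3 poolings of size {pool}")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    c_in = 1
    conv_hook = None
    for c_out in filters:
        layers.append(Conv1D(c_in, c_out, kernel, rng))
        layers.append(ReLU())
        conv_hook = len(layers) - 1  # output of the ReLU after the conv
        layers.append(MaxPool1D(pool))
        layers.append(Dropout(dropout))
        c_in = c_out
    layers.append(Flatten())
    flat = time * filters[-1]
    layers.append(Dense(flat, 2, rng))
    return Model(layers, input_len, conv_hook=conv_hook,
                 penultimate_hook=len(layers) - 2)


# ---------------------------------------------------------------------------
# high-level helpers

def predict_proba(model: Model, x: np.ndarray) -> np.ndarray:
    return _softmax(model.forward(x))


def predict_label_indices(model: Model, x: np.ndarray) -> np.ndarray:
    """0/1 class indices; exact ties resolve to class 0 (no pain)."""
    logits = model.forward(x)
    return (logits[:, 1] > logits[:, 0]).astype(int)


def train_classifier(model: Model, x: np.ndarray, y: np.ndarray,
                     cfg: TrainConfig = TrainConfig()) -> list[float]:
    """Train on (n, time, 1) inputs with integer labels; returns loss history."""
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if len(set(np.asarray(y).tolist())) < 2:
        raise ValueError("training set must contain both classes")
    return model.fit(x, y, cfg)


def penultimate_features(model: Model, x: np.ndarray) -> np.ndarray:
    """Activations feeding the final classification layer, one row per window."""
    if not model.trained:
        raise ValueError("model has not been trained")
    if model.penultimate_hook is None:
        raise ValueError("model exposes no penultimate layer")
    outs = model._forward_collect(x)
    return outs[model.penultimate_hook]
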