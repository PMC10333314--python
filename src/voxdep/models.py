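"""Network families for depression detection and severity estimation.

Four families operate on context windows (C contiguous segment-level feature
vectors of width L):

* ``mkcnn`` — multi-kernel CNN: three parallel branches with full-width
  kernels of heights 3, 4 and 5 (50 channels each, stride 1, valid padding),
  each followed by a kernel-4 temporal convolution (50 channels), ReLU
  throughout; branch outputs are flattened, concatenated, and passed through
  a 100-unit FC layer before the output head.
* ``lstm`` — 2 LSTM layers with 128 units (dropout 0.4 between layers); the
  last-timestep state feeds the 100-unit FC layer and the head.
* ``dnn`` — baseline fully-connected stack (128, 64, 128 ReLU units) on a
  single segment vector (or a mean-pooled window), straight to the head.
* ``ce_c`` / ``ce_l`` — two-branch fusion ("combining embeddings"): each
  stream runs its own MK-CNN or LSTM block plus 100-unit FC layer; the two
  100-d outputs are combined by elementwise product and passed to the head.
  (A literal scalar inner product is available via ``fusion="scalar"``.)

The detection head is a 2-unit softmax trained with weighted negative
log-likelihood; the severity head is a single linear unit trained with mean
squared error.  Training uses Adam (beta1 0.9, beta2 0.99), learning rate
5e-4, 50 epochs, batch size 128 by default, with no early stopping.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) and accept
``X`` of shape (n, C, L) — for the fusion families the two streams are
concatenated along the feature axis and split at ``split_at``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _nn
from ._nn import Adam, Dense, Dropout, DTYPE, LSTMLayer, Param, ReLU, TemporalConv

FAMILIES = ("mkcnn", "lstm", "dnn", "ce_c", "ce_l")

KERNEL_HEIGHTS = (3, 4, 5)
CHANNELS = 50
SECOND_KERNEL = 4
LSTM_UNITS = 128
LSTM_LAYERS = 2
FC_UNITS = 100
DNN_HIDDEN = (128, 64, 128)
MIN_CONTEXT = max(KERNEL_HEIGHTS) + SECOND_KERNEL - 1  # 8


def mkcnn_flat_size(context: int, channels: int = CHANNELS,
                    kernel_heights=KERNEL_HEIGHTS,
                    second_kernel: int = SECOND_KERNEL) -> int:
    """Flattened concatenated size after the two valid convolutions.

    Each branch with kernel height k keeps C-k+1 then C-k+1-(k2-1) time
    steps; every branch must retain at least one step, hence C >= 8 for the
    default kernels.
    """
    sizes = [context - k + 1 - (second_kernel - 1) for k in kernel_heights]
    if min(sizes) < 1:
        raise ValueError(
            f"context {context} too small for kernels {kernel_heights}; need "
            f">= {max(kernel_heights) + second_kernel - 1}"
        )
    return channels * sum(sizes)


# ---------------------------------------------------------------------------
# network blocks


class _MKCNNBlock:
    """(B, C, L) -> (B, flat) through the three convolutional branches."""

    def __init__(self, context, n_features, rng, dropout=0.3):
        self.flat_size = mkcnn_flat_size(context)
        self.branches = []
        for k in KERNEL_HEIGHTS:
            self.branches.append({
                "conv1": TemporalConv(k, n_features, CHANNELS, rng),
                "relu1": ReLU(),
                "conv2": TemporalConv(SECOND_KERNEL, CHANNELS, CHANNELS, rng),
                "relu2": ReLU(),
            })
        self.drop = Dropout(dropout, rng)
        self.out_dim = self.flat_size

    def params(self):
        out = []
        for br in self.branches:
            out += br["conv1"].params() + br["conv2"].params()
        return out

    def forward(self, x, train):
        outs, self._shapes = [], []
        for br in self.branches:
            h = br["conv1"].forward(x, train)
            h = br["relu1"].forward(h, train)
            h = br["conv2"].forward(h, train)
            h = br["relu2"].forward(h, train)
            self._shapes.append(h.shape)
            outs.append(h.reshape(h.shape[0], -1))
        return self.drop.forward(np.concatenate(outs, axis=1), train)

    def backward(self, grad):
        grad = self.drop.backward(grad)
        dx = None
        offset = 0
        for br, shape in zip(self.branches, self._shapes):
            width = shape[1] * shape[2]
            g = grad[:, offset:offset + width].reshape(shape)
            offset += width
            g = br["relu2"].backward(g)
            g = br["conv2"].backward(g)
            g = br["relu1"].backward(g)
            g = br["conv1"].backward(g)
            dx = g if dx is None else dx + g
        return dx


class _LSTMBlock:
    """(B, C, L) -> (B, 128): 2-layer LSTM, last timestep."""

    def __init__(self, context, n_features, rng, dropout=0.4):
        self.lstm1 = LSTMLayer(n_features, LSTM_UNITS, rng)
        self.drop = Dropout(dropout, rng)
        self.lstm2 = LSTMLayer(LSTM_UNITS, LSTM_UNITS, rng)
        self.out_dim = LSTM_UNITS

    def params(self):
        return self.lstm1.params() + self.lstm2.params()

    def forward(self, x, train):
        h = self.lstm1.forward(x, train)
        h = self.drop.forward(h, train)
        h = self.lstm2.forward(h, train)
        self._seq_shape = h.shape
        return h[:, -1, :]

    def backward(self, grad):
        dseq = np.zeros(self._seq_shape, dtype=DTYPE)
        dseq[:, -1, :] = grad
        g = self.lstm2.backward(dseq)
        g = self.drop.backward(g)
        return self.lstm1.backward(g)


class _DNNBlock:
    """(B, L) -> (B, 128): the 128-64-128 ReLU baseline stack."""

    def __init__(self, context, n_features, rng, dropout=0.3):
        dims = (n_features,) + DNN_HIDDEN
        self.layers = []
        for a, b in zip(dims[:-1], dims[1:]):
            self.layers += [Dense(a, b, rng), ReLU(), Dropout(dropout, rng)]
        self.out_dim = DNN_HIDDEN[-1]

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class _Stream:
    """A block followed by the 100-unit FC layer (ReLU, dropout).

    ``bias_shift`` offsets the FC bias at initialisation; the fusion
    families start at +1 so the elementwise product of two mostly-active
    ReLU vectors behaves quasi-additively early in training instead of
    silencing gradients through dead units.
    """

    def __init__(self, block, rng, dropout_fc=0.3, bias_shift=0.0):
        self.block = block
        self.fc = Dense(block.out_dim, FC_UNITS, rng)
        if bias_shift:
            self.fc.b.value += np.float32(bias_shift)
        self.relu = ReLU()
        self.drop = Dropout(dropout_fc, rng)
        self.out_dim = FC_UNITS

    def params(self):
        return self.block.params() + self.fc.params()

    def forward(self, x, train):
        h = self.block.forward(x, train)
        h = self.fc.forward(h, train)
        h = self.relu.forward(h, train)
        return self.drop.forward(h, train)

    def backward(self, grad):
        g = self.drop.backward(grad)
        g = self.relu.backward(g)
        g = self.fc.backward(g)
        return self.block.backward(g)


class Network:
    """A complete network: stream(s) plus the task head.

    ``n_outputs`` is 2 for detection (softmax over healthy/depressed logits)
    and 1 for severity regression.
    """

    def __init__(self, family: str, n_outputs: int, context: int,
                 input_dim: int, rng: np.random.Generator,
                 input_dim_b: int | None = None, fusion: str = "hadamard",
                 dropout_cnn: float = 0.3, dropout_lstm: float = 0.4,
                 dropout_fc: float = 0.3):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.fusion = fusion
        block_for = {
            "mkcnn": lambda d: _MKCNNBlock(context, d, rng, dropout_cnn),
            "lstm": lambda d: _LSTMBlock(context, d, rng, dropout_lstm),
            "dnn": lambda d: _DNNBlock(context, d, rng, dropout_fc),
        }
        if family in ("mkcnn", "lstm"):
            self.stream_a = _Stream(block_for[family](input_dim), rng, dropout_fc)
            self.streams = [self.stream_a]
            head_in = FC_UNITS
        elif family == "dnn":
            self.stream_a = block_for["dnn"](input_dim)
            self.streams = [self.stream_a]
            head_in = self.stream_a.out_dim
        else:
            if input_dim_b is None:
                raise ValueError("fusion families need input_dim_b")
            kind = "mkcnn" if family == "ce_c" else "lstm"
            self.stream_a = _Stream(block_for[kind](input_dim), rng, dropout_fc,
                                    bias_shift=1.0)
            self.stream_b = _Stream(block_for[kind](input_dim_b), rng, dropout_fc,
                                    bias_shift=1.0)
            self.streams = [self.stream_a, self.stream_b]
            head_in = 1 if fusion == "scalar" else FC_UNITS
        self.head = Dense(head_in, n_outputs, rng)
        self.n_outputs = n_outputs

    def params(self) -> list[Param]:
        out = []
        for s in self.streams:
            out += s.params()
        return out + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x, train: bool = False, x_b=None):
        if len(self.streams) == 1:
            h = self.stream_a.forward(x, train)
        else:
            ha = self.stream_a.forward(x, train)
            hb = self.stream_b.forward(x_b, train)
            self._ha, self._hb = ha, hb
            h = ha * hb
            if self.fusion == "scalar":
                h = h.sum(axis=1, keepdims=True)
        return self.head.forward(h, train)

    def backward(self, grad):
        g = self.head.backward(grad)
        if len(self.streams) == 1:
            return self.stream_a.backward(g)
        if self.fusion == "scalar":
            g = np.broadcast_to(g, self._ha.shape).copy()
        ga = g * self._hb
        gb = g * self._ha
        dxa = self.stream_a.backward(ga)
        dxb = self.stream_b.backward(gb)
        return dxa, dxb


# ---------------------------------------------------------------------------
# functional forward passes (thin wrappers over Network)


def mkcnn_forward(window: np.ndarray, net: Network) -> np.ndarray:
    """Evaluate an MK-CNN network on a single C x L window."""
    return net.forward(np.asarray(window, dtype=DTYPE)[None])[0]


def lstm_forward(window: np.ndarray, net: Network) -> np.ndarray:
    return net.forward(np.asarray(window, dtype=DTYPE)[None])[0]


def dnn_forward(vector: np.ndarray, net: Network) -> np.ndarray:
    return net.forward(np.asarray(vector, dtype=DTYPE)[None])[0]


def ce_forward(window_a: np.ndarray, window_b: np.ndarray, net: Network) -> np.ndarray:
    a = np.asarray(window_a, dtype=DTYPE)[None]
    b = np.asarray(window_b, dtype=DTYPE)[None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("both streams must share the temporal context")
    return net.forward(a, x_b=b)[0]


# ---------------------------------------------------------------------------
# estimators


class _WindowNetBase(BaseEstimator):
    """Shared fit machinery for the window-level networks."""

    _task_outputs = 2

    def __init__(self, family="mkcnn", split_at=None, fusion="hadamard",
                 epochs=50, batch_size=128, learning_rate=5e-4,
                 beta1=0.9, beta2=0.99, dropout_cnn=0.3, dropout_lstm=0.4,
                 dropout_fc=0.3, pool=False, random_state=0):
        self.family = family
        self.split_at = split_at
        self.fusion = fusion
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.dropout_cnn = dropout_cnn
        self.dropout_lstm = dropout_lstm
        self.dropout_fc = dropout_fc
        self.pool = pool
        self.random_state = random_state

    # -- input handling ----------------------------------------------------
    def _prepare_X(self, X):
        X = np.asarray(X, dtype=DTYPE)
        if self.family == "dnn":
            if X.ndim == 3:
                if not self.pool:
                    raise ValueError(
                        "dnn consumes single segment vectors; pass pool=True "
                        "to mean-pool windows"
                    )
                X = X.mean(axis=1)
            if X.ndim != 2:
                raise ValueError("dnn expects (n, L) input")
            return X, None
        if X.ndim != 3:
            raise ValueError(f"{self.family} expects (n, C, L) windows")
        if self.family in ("ce_c", "ce_l"):
            if self.split_at is None:
                raise ValueError("fusion families require split_at")
            return X[:, :, :self.split_at], X[:, :, self.split_at:]
        return X, None

    def _build(self, Xa, Xb, rng):
        context = 1 if Xa.ndim == 2 else Xa.shape[1]
        return Network(
            self.family, self._task_outputs, context, Xa.shape[-1], rng,
            input_dim_b=None if Xb is None else Xb.shape[-1],
            fusion=self.fusion, dropout_cnn=self.dropout_cnn,
            dropout_lstm=self.dropout_lstm, dropout_fc=self.dropout_fc,
        )

    def _fit_loop(self, Xa, Xb, targets, sample_weight, loss_fn):
        if Xa.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        net = self._build(Xa, Xb, rng)
        opt = Adam(net.params(), lr=self.learning_rate,
                   beta1=self.beta1, beta2=self.beta2)
        n = Xa.shape[0]
        curve = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses, counts = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                out = net.forward(Xa[idx], train=True,
                                  x_b=None if Xb is None else Xb[idx])
                loss, grad = loss_fn(out, idx, sample_weight)
                net.backward(grad)
                opt.step()
                losses += loss * len(idx)
                counts += len(idx)
            curve.append(losses / counts)
        self.network_ = net
        self.loss_curve_ = curve
        self.n_features_in_ = Xa.shape[-1]
        self.context_ = 1 if Xa.ndim == 2 else Xa.shape[1]
        self.input_dim_ = Xa.shape[-1]
        self.input_dim_b_ = None if Xb is None else Xb.shape[-1]
        return self

    def _forward_eval(self, X, batch=512):
        Xa, Xb = self._prepare_X(X)
        outs = []
        for start in range(0, Xa.shape[0], batch):
            outs.append(self.network_.forward(
                Xa[start:start + batch], train=False,
                x_b=None if Xb is None else Xb[start:start + batch]))
        return np.concatenate(outs, axis=0)


class WindowClassifier(ClassifierMixin, _WindowNetBase):
    """Depression detection on context windows (2-unit softmax head).

    ``class_weight`` may be None, "balanced" (inverse-frequency weights
    normalised to mean 1, recomputed from the training labels) or a mapping
    class -> weight.
    """

    _task_outputs = 2

    def __init__(self, family="mkcnn", split_at=None, fusion="hadamard",
                 epochs=50, batch_size=128, learning_rate=5e-4,
                 beta1=0.9, beta2=0.99, dropout_cnn=0.3, dropout_lstm=0.4,
                 dropout_fc=0.3, pool=False, random_state=0,
                 class_weight="balanced"):
        super().__init__(family=family, split_at=split_at, fusion=fusion,
                         epochs=epochs, batch_size=batch_size,
                         learning_rate=learning_rate, beta1=beta1, beta2=beta2,
                         dropout_cnn=dropout_cnn, dropout_lstm=dropout_lstm,
                         dropout_fc=dropout_fc, pool=pool,
                         random_state=random_state)
        self.class_weight = class_weight

    def fit(self, X, y):
        from .train_eval import compute_class_weights

        Xa, Xb = self._prepare_X(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.class_weight == "balanced":
            if self.classes_.size < 2:
                raise ValueError("training set contains a single class")
            w = compute_class_weights(y)
            weights = w[y].astype(np.float64)
        elif self.class_weight is None:
            weights = np.ones(len(y))
        else:
            weights = np.asarray([self.class_weight[c] for c in y], dtype=np.float64)

        def loss_fn(out, idx, _):
            return _nn.nll_loss_grad(out, y[idx], weights[idx])

        return self._fit_loop(Xa, Xb, y, weights, loss_fn)

    def predict_proba(self, X):
        return _nn.softmax(self._forward_eval(X).astype(np.float64))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


class WindowRegressor(RegressorMixin, _WindowNetBase):
    """Severity estimation on context windows (single linear output unit).

    Targets are z-scored internally during training (``standardize_targets``)
    and predictions mapped back to the severity scale; the reported loss
    curve is in standardized units.
    """

    _task_outputs = 1

    def __init__(self, family="mkcnn", split_at=None, fusion="hadamard",
                 epochs=50, batch_size=128, learning_rate=5e-4,
                 beta1=0.9, beta2=0.99, dropout_cnn=0.3, dropout_lstm=0.4,
                 dropout_fc=0.3, pool=False, random_state=0,
                 standardize_targets=True):
        super().__init__(family=family, split_at=split_at, fusion=fusion,
                         epochs=epochs, batch_size=batch_size,
                         learning_rate=learning_rate, beta1=beta1, beta2=beta2,
                         dropout_cnn=dropout_cnn, dropout_lstm=dropout_lstm,
                         dropout_fc=dropout_fc, pool=pool,
                         random_state=random_state)
        self.standardize_targets = standardize_targets

    def fit(self, X, y):
        Xa, Xb = self._prepare_X(X)
        y = np.asarray(y, dtype=np.float64)
        if self.standardize_targets:
            self.y_mean_ = float(y.mean())
            self.y_scale_ = float(max(y.std(), 1e-8))
        else:
            self.y_mean_, self.y_scale_ = 0.0, 1.0
        t = (y - self.y_mean_) / self.y_scale_

        def loss_fn(out, idx, _):
            loss, grad = _nn.mse_loss_grad(out[:, 0], t[idx])
            return loss, grad[:, None]

        return self._fit_loop(Xa, Xb, t, None, loss_fn)

    def predict(self, X):
        out = self._forward_eval(X)[:, 0].astype(np.float64)
        return out * self.y_scale_ + self.y_mean_


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(estimator, path) -> None:
    """Serialize a fitted estimator: constructor params, dims and weights."""
    import json

    meta = {
        "estimator": type(estimator).__name__,
        "params": estimator.get_params(),
        "context": estimator.context_,
        "input_dim": estimator.input_dim_,
        "input_dim_b": estimator.input_dim_b_,
    }
    if isinstance(estimator, WindowClassifier):
        meta["classes"] = estimator.classes_.tolist()
    else:
        meta["y_mean"] = estimator.y_mean_
        meta["y_scale"] = estimator.y_scale_
    arrays = {f"param_{i}": p.value for i, p in
              enumerate(estimator.network_.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Rebuild a fitted estimator from :func:`save_checkpoint` output."""
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cls = WindowClassifier if meta["estimator"] == "WindowClassifier" else WindowRegressor
    est = cls(**meta["params"])
    rng = np.random.default_rng(est.random_state)
    net = Network(
        est.family, cls._task_outputs, meta["context"], meta["input_dim"], rng,
        input_dim_b=meta["input_dim_b"], fusion=est.fusion,
        dropout_cnn=est.dropout_cnn, dropout_lstm=est.dropout_lstm,
        dropout_fc=est.dropout_fc,
    )
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"param_{i}"]
    est.network_ = net
    est.context_ = meta["context"]
    est.input_dim_ = meta["input_dim"]
    est.input_dim_b_ = meta["input_dim_b"]
    est.n_features_in_ = meta["input_dim"]
    est.loss_curve_ = []
    if cls is WindowClassifier:
        est.classes_ = np.asarray(meta["classes"])
    else:
        est.y_mean_ = meta["y_mean"]
        est.y_scale_ = meta["y_scale"]
    return est
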