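"""Fast-compression residual convolutional network (FCRes-CNN) in NumPy.

The network classifies sparse-code vectors (length N, one channel).  Its
architecture is a fast down-sampling module — a convolution with a large
stride (default 3) replacing pooling, followed by dropout and batch
normalization — then a stack of residual convolution modules, each two
serial convolutions with an identity shortcut (output = F(input) + input,
i.e. the branch learns the residual F(x) = H(x) - x), dropout and max
pooling, and finally a classification module: a width-1 convolution for
channel reduction, flatten, dropout, and a dense softmax head trained with
categorical cross-entropy under Adam.

Everything is implemented directly on NumPy arrays with explicit forward
and backward passes; a single integer seed drives weight initialization,
dropout masks and shuffling, so training is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainedNetwork",
    "build_network",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv1d:
    """1-D convolution with 'same'-style padding: out_len = ceil(L / stride)."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_len(self, L: int) -> int:
        return -(-L // self.stride)

    def _geometry(self, L):
        out_len = self.out_len(L)
        pad_total = max((out_len - 1) * self.stride + self.kernel - L, 0)
        pad_l = pad_total // 2
        return out_len, pad_l, pad_total - pad_l

    def forward(self, x, training, rng):
        B, C, L = x.shape
        out_len, pl, pr = self._geometry(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # gather one strided slice per kernel offset (no fancy indexing)
        patches = np.empty((B, C, self.kernel, out_len))
        span = (out_len - 1) * self.stride + 1
        for ki in range(self.kernel):
            patches[:, :, ki, :] = xp[:, :, ki : ki + span : self.stride]
        cols = patches.reshape(B, C * self.kernel, out_len)
        y = np.einsum("of,bfl->bol", self.W.reshape(self.out_ch, -1), cols)
        y += self.b[None, :, None]
        self._cache = (cols, x.shape, pl, pr)
        return y

    def backward(self, dy):
        cols, x_shape, pl, pr = self._cache
        B, C, L = x_shape
        out_len = dy.shape[2]
        self.dW += np.einsum("bol,bfl->of", dy, cols).reshape(self.W.shape)
        self.db += dy.sum(axis=(0, 2))
        dcols = np.einsum("of,bol->bfl", self.W.reshape(self.out_ch, -1), dy)
        dpatches = dcols.reshape(B, C, self.kernel, out_len)
        dxp = np.zeros((B, C, L + pl + pr))
        span = (out_len - 1) * self.stride + 1
        # slices within one kernel offset never overlap, so += suffices
        for ki in range(self.kernel):
            dxp[:, :, ki : ki + span : self.stride] += dpatches[:, :, ki, :]
        return dxp[:, :, pl : pl + L]

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, ch, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.dgamma = np.zeros(ch)
        self.dbeta = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, training)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, std, training = self._cache
        self.dgamma += (dy * xhat).sum(axis=(0, 2))
        self.dbeta += dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] / std[None, :, None]
        if not training:
            return g * dy
        n = dy.shape[0] * dy.shape[2]
        mean_dy = dy.mean(axis=(0, 2))[None, :, None]
        mean_dyx = (dy * xhat).mean(axis=(0, 2))[None, :, None]
        return g * (dy - mean_dy - xhat * mean_dyx)

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    params: list = []


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    params: list = []


class MaxPool1d:
    """Non-overlapping max pooling; a trailing partial window is dropped."""

    def __init__(self, size=2):
        self.size = size

    def out_len(self, L: int) -> int:
        return L // self.size

    def forward(self, x, training, rng):
        B, C, L = x.shape
        n = self.out_len(L)
        xr = x[:, :, : n * self.size].reshape(B, C, n, self.size)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._in_shape
        n = dy.shape[2]
        dxr = np.zeros((B, C, n, self.size))
        bi, ci, ni = np.ogrid[:B, :C, :n]
        dxr[bi, ci, ni, self._arg] = dy
        dx = np.zeros((B, C, L))
        dx[:, :, : n * self.size] = dxr.reshape(B, C, n * self.size)
        return dx

    params: list = []


class Flatten:
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    params: list = []


class Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ResidualBlock:
    """Two serial convolutions with an identity shortcut, then dropout and pool.

    output = pool(dropout(F(x) + shortcut(x))) where F = conv-BN-ReLU-conv-BN
    and shortcut is the identity when channel counts match, else a width-1
    projection convolution.  The pre-pool sum is cached so the identity
    contract (zeroed branch => output equals input) is directly inspectable.
    """

    def __init__(self, in_ch, filters, kernel, dropout, pool, rng):
        self.branch = [
            Conv1d(in_ch, filters, kernel, 1, rng),
            BatchNorm1d(filters),
            ReLU(),
            Conv1d(filters, filters, kernel, 1, rng),
            BatchNorm1d(filters),
        ]
        self.shortcut = None if in_ch == filters else Conv1d(in_ch, filters, 1, 1, rng)
        self.dropout = Dropout(dropout)
        self.pool = MaxPool1d(pool)
        self.prepool = None

    def out_len(self, L: int) -> int:
        return self.pool.out_len(L)

    def zero_residual_branch(self) -> None:
        """Force F === 0 so the block computes the identity (up to pooling)."""
        for layer in self.branch:
            if isinstance(layer, Conv1d):
                layer.W[:] = 0.0
                layer.b[:] = 0.0
            elif isinstance(layer, BatchNorm1d):
                layer.gamma[:] = 0.0
                layer.beta[:] = 0.0

    def forward(self, x, training, rng):
        h = x
        for layer in self.branch:
            h = layer.forward(h, training, rng)
        s = x if self.shortcut is None else self.shortcut.forward(x, training, rng)
        self.prepool = h + s
        out = self.dropout.forward(self.prepool, training, rng)
        return self.pool.forward(out, training, rng)

    def backward(self, dy):
        d = self.pool.backward(dy)
        d = self.dropout.backward(d)
        dbranch = d
        for layer in reversed(self.branch):
            dbranch = layer.backward(dbranch)
        dshort = d if self.shortcut is None else self.shortcut.backward(d)
        return dbranch + dshort

    @property
    def params(self):
        out = []
        for layer in self.branch:
            out.extend(layer.params)
        if self.shortcut is not None:
            out.extend(self.shortcut.params)
        return out


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults follow the intended operating point: stride-3 fast
    down-sampling, three residual modules, learning rate 0.001 and batch
    size 2,500 (larger than the usual trial count, hence effectively
    full-batch training).
    """

    input_length: int
    n_classes: int = 2
    fds_stride: int = 3
    fds_filters: int = 16
    fds_kernel: int = 7
    res_blocks: int = 3
    res_filters: tuple = (16, 32, 32)
    res_kernel: int = 3
    pool_size: int = 2
    head_filters: int = 8
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 2500
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.fds_stride < 2:
            raise ValueError("fds_stride must be >= 2 (fast down-sampling)")
        if self.res_blocks < 1:
            raise ValueError("res_blocks must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_length < self.fds_kernel:
            raise ValueError(
                f"input_length {self.input_length} < fds_kernel {self.fds_kernel}"
            )
        if len(self.res_filters) < self.res_blocks:
            raise ValueError("res_filters must name one filter count per block")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[:] = 0.0


class _FCResNet:
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.fds = [
            Conv1d(1, cfg.fds_filters, cfg.fds_kernel, cfg.fds_stride, rng),
            Dropout(cfg.dropout_rate),
            BatchNorm1d(cfg.fds_filters),
            ReLU(),
        ]
        L = self.fds[0].out_len(cfg.input_length)
        self.blocks = []
        in_ch = cfg.fds_filters
        for i in range(cfg.res_blocks):
            f = cfg.res_filters[i]
            blk = ResidualBlock(in_ch, f, cfg.res_kernel, cfg.dropout_rate, cfg.pool_size, rng)
            self.blocks.append(blk)
            L = blk.out_len(L)
            in_ch = f
        if L < 1:
            min_len = cfg.fds_stride * cfg.pool_size**cfg.res_blocks
            raise ValueError(
                f"input_length {cfg.input_length} too short for the stride/pool "
                f"chain; needs at least {min_len} samples"
            )
        self.head = [
            Conv1d(in_ch, cfg.head_filters, 1, 1, rng),
            ReLU(),
            Flatten(),
            Dropout(cfg.dropout_rate),
            Dense(L * cfg.head_filters, cfg.n_classes, rng),
        ]
        self.final_length = L

    def _all_layers(self):
        return [*self.fds, *self.blocks, *self.head]

    def forward(self, x, training, rng):
        for layer in self._all_layers():
            x = layer.forward(x, training, rng)
        return x  # logits

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self._all_layers()):
            d = layer.backward(d)
        return d

    @property
    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.params))

    def layer_inventory(self) -> list[str]:
        names = []
        for layer in self._all_layers():
            names.append(type(layer).__name__)
        return names


@dataclass
class TrainedNetwork:
    """A (possibly untrained) FCRes-CNN with its config and training history."""

    config: NetworkConfig
    net: _FCResNet
    rng: np.random.Generator
    history: list[dict] = field(default_factory=list)

    def parameter_count(self) -> int:
        return self.net.parameter_count()

    def layer_inventory(self) -> list[str]:
        return self.net.layer_inventory()


def build_network(cfg: NetworkConfig) -> TrainedNetwork:
    """Instantiate the FCRes-CNN with seeded weight initialization."""
    rng = np.random.default_rng(cfg.seed)
    return TrainedNetwork(config=cfg, net=_FCResNet(cfg, rng), rng=rng)


def _state_arrays(net: _FCResNet) -> list[np.ndarray]:
    """All arrays needed for inference: parameters plus batch-norm running
    statistics, in deterministic layer order."""
    arrays = [p for p, _ in net.params]
    for layer in net._all_layers():
        bns = []
        if isinstance(layer, BatchNorm1d):
            bns = [layer]
        elif isinstance(layer, ResidualBlock):
            bns = [l for l in layer.branch if isinstance(l, BatchNorm1d)]
        for bn in bns:
            arrays.extend([bn.running_mean, bn.running_var])
    return arrays


def save_checkpoint(trained: TrainedNetwork, path) -> None:
    """Write config + weights + batch-norm statistics to an .npz file."""
    import json

    from dataclasses import asdict

    arrays = _state_arrays(trained.net)
    np.savez(
        path,
        config=np.frombuffer(
            json.dumps(asdict(trained.config)).encode(), dtype=np.uint8
        ),
        **{f"arr_{i}": a for i, a in enumerate(arrays)},
    )


def load_checkpoint(path) -> TrainedNetwork:
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config"]).decode())
        cfg_dict["res_filters"] = tuple(cfg_dict["res_filters"])
        cfg = NetworkConfig(**cfg_dict)
        trained = build_network(cfg)
        arrays = _state_arrays(trained.net)
        for i, a in enumerate(arrays):
            a[...] = data[f"arr_{i}"]
    return trained


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _epoch_metrics(net, rng, X, y0, n_classes):
    logits = net.forward(X, training=False, rng=rng)
    probs = _softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(len(y0)), y0], 1e-12, 1.0)).mean()
    acc = float((probs.argmax(axis=1) == y0).mean())
    return float(loss), acc


def train(
    trained: TrainedNetwork,
    codes: np.ndarray,
    labels: np.ndarray,
    val_fraction: float = 0.0,
    **overrides,
) -> TrainedNetwork:
    """Train in place by mini-batch Adam on categorical cross-entropy.

    ``labels`` use the 1-based class convention; the effective batch is
    min(batch_size, n_samples), so a batch size exceeding the trial count
    degrades gracefully to full-batch gradient descent.  Config fields may
    be overridden per call (e.g. ``epochs=50``).
    """
    cfg = replace(trained.config, **overrides) if overrides else trained.config
    codes = np.asarray(codes, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if codes.ndim != 2 or codes.shape[0] != labels.size:
        raise ValueError("codes must be (n_samples, input_length) matching labels")
    if codes.shape[1] != cfg.input_length:
        raise ValueError(
            f"code length {codes.shape[1]} != configured input_length {cfg.input_length}"
        )
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    y0 = labels - 1  # 1-based -> 0-based
    if y0.min() < 0 or y0.max() >= cfg.n_classes:
        raise ValueError(f"labels must lie in 1..{cfg.n_classes}")

    rng = trained.rng
    net = trained.net
    X = codes[:, None, :]
    n = X.shape[0]

    if val_fraction > 0:
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, yv = X[val_idx], y0[val_idx]
        X, y0 = X[tr_idx], y0[tr_idx]
        n = X.shape[0]
    else:
        Xv = yv = None

    batch = min(cfg.batch_size, n)
    opt = _Adam(net.params, cfg.learning_rate)
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch):
            idx = perm[start : start + batch]
            xb, yb = X[idx], y0[idx]
            opt.zero_grad()
            logits = net.forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, 1.0)).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss became non-finite at epoch {_epoch}; "
                    "lower the learning rate or check the input scaling"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            net.backward((probs - onehot) / len(yb))
            opt.step()
        tr_loss, tr_acc = _epoch_metrics(net, rng, X, y0, cfg.n_classes)
        if Xv is not None:
            va_loss, va_acc = _epoch_metrics(net, rng, Xv, yv, cfg.n_classes)
        else:
            va_loss = va_acc = None
        trained.history.append(
            {
                "epoch": len(trained.history),
                "train_loss": tr_loss,
                "train_acc": tr_acc,
                "val_loss": va_loss,
                "val_acc": va_acc,
            }
        )
    return trained


def predict(trained: TrainedNetwork, codes: np.ndarray):
    """Class probabilities and 1-based argmax labels for a batch of codes."""
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 2 or codes.shape[1] != trained.config.input_length:
        raise ValueError(
            f"codes must be (n, {trained.config.input_length}), got {codes.shape}"
        )
    logits = trained.net.forward(codes[:, None, :], training=False, rng=trained.rng)
    probs = _softmax(logits)
    labels = probs.argmax(axis=1) + 1  # argmax breaks ties toward the lower class
    return probs, labels
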