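"""One-dimensional convolutional sequence regressor for CO2 time series.

Maps a fixed-length (default 2400-sample, i.e. 12 s at 200 Hz) expired
CO2 sequence to the two spirometric targets (FEV1, FVC).  Architecture:
three stacked blocks of {valid 1-D convolution (kernel width 5, ReLU),
max-pooling (width 5), dropout}, with 32 / 64 / 32 filters, then a
flatten and a dense layer to 2 outputs.  With the default input length
the conv/pool length recurrence L -> floor((L - 4) / 5) gives
2400 -> 2396 -> 479 -> 475 -> 95 -> 91 -> 18 and a flatten width of
18 * 32 = 576; trainable parameters are 192 / 10,304 / 10,272 / 1,154
for the three conv layers and the dense head.

The network, its backpropagation and its SGD loop are implemented
directly on NumPy arrays (float32, im2col convolutions), which keeps
training deterministic for a fixed seed.  Training minimizes mean
squared error with a learning rate that starts at 0.03 and decays by a
fixed factor per epoch; gradients are clipped in global norm for
stability.  Dropout is active only during training, so inference is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .errors import NotFittedError, PreprocessingError, TrainingDivergedError

__all__ = [
    "NetworkConfig", "CapnoCNN",
    "preprocess_sequence", "build_network", "count_parameters",
    "train_network", "predict_sequence", "save_network", "load_network",
]

PREDICTION_FLOOR = 0.1  # L
ONSET_THRESHOLD = 2.0   # mmHg; first sample above marks expiration onset
INPUT_SCALE = 1.0 / 40.0


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters of the sequence network."""

    input_length: int = 2400
    filters: tuple[int, int, int] = (32, 64, 32)
    kernel: int = 5
    pool: int = 5
    dropout: float = 0.1
    epochs: int = 100
    learning_rate: float = 0.03
    lr_decay: float = 0.97      # multiplicative, per epoch
    batch_size: int = 32
    grad_clip: float = 5.0      # global-norm gradient clip
    seed: int = 0

    def __post_init__(self):
        if self.kernel < 1 or any(f < 1 for f in self.filters):
            raise ValueError("kernel width and filter counts must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def layer_lengths(self) -> list[tuple[int, int]]:
        """(conv output length, pool output length) per block.

        Raises ValueError if the input is too short for three blocks.
        """
        lengths = []
        length = self.input_length
        for i in range(3):
            conv_len = length - self.kernel + 1
            pool_len = conv_len // self.pool
            if conv_len < 1 or pool_len < 1:
                raise ValueError(
                    f"input_length {self.input_length} too short for block {i + 1}"
                )
            lengths.append((conv_len, pool_len))
            length = pool_len
        return lengths

    @property
    def flatten_width(self) -> int:
        return self.layer_lengths()[-1][1] * self.filters[-1]


def preprocess_sequence(raw_co2, input_length: int = 2400) -> np.ndarray:
    """Trim a raw CO2 series to the network input window and scale it.

    Expiration onset is the first sample exceeding 2 mmHg; the window is
    the ``input_length`` samples from onset (12 s at 200 Hz by default).
    Shorter series are right-padded with their final value.  Values are
    scaled by 1/40 mmHg so inputs are O(1).
    """
    raw = np.asarray(raw_co2, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise PreprocessingError("raw CO2 series must be 1-D with >= 2 samples")
    above = np.flatnonzero(raw > ONSET_THRESHOLD)
    if above.size == 0:
        raise PreprocessingError(
            f"no expiration onset: CO2 never exceeds {ONSET_THRESHOLD} mmHg"
        )
    window = raw[above[0]: above[0] + input_length]
    if window.size < input_length:
        window = np.concatenate(
            [window, np.full(input_length - window.size, window[-1])]
        )
    return (window * INPUT_SCALE).astype(np.float32)


# ---------------------------------------------------------------------------
# layers


class _Conv1D:
    """Valid 1-D convolution + ReLU, stride 1, im2col implementation."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, L, C_in) -> (B, L-k+1, C_out)
        b, length, c_in = x.shape
        l_out = length - self.k + 1
        col = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        # col: (B, L_out, C_in, k) -> (B*L_out, C_in*k)
        self._col = np.ascontiguousarray(col).reshape(b * l_out, c_in * self.k)
        z = self._col @ self.w + self.b
        self._mask = z > 0
        self._shape_in = x.shape
        return np.where(self._mask, z, 0.0).reshape(b, l_out, -1)

    def backward(self, grad: np.ndarray):
        b, l_out, c_out = grad.shape
        _, length, c_in = self._shape_in
        g = grad.reshape(b * l_out, c_out) * self._mask
        self.dw = self._col.T @ g
        self.db = g.sum(axis=0)
        dcol = (g @ self.w.T).reshape(b, l_out, c_in, self.k)
        dx = np.zeros(self._shape_in, dtype=np.float32)
        for j in range(self.k):
            dx[:, j: j + l_out, :] += dcol[:, :, :, j]
        return dx

    def step(self, lr: float, scale: float):
        self.w -= lr * scale * self.dw
        self.b -= lr * scale * self.db


class _MaxPool1D:
    def __init__(self, width: int):
        self.width = width
        self.n_params = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        l_out = length // self.width
        self._trim = (x.shape, l_out)
        xt = x[:, : l_out * self.width, :].reshape(b, l_out, self.width, c)
        self._argmax = xt.argmax(axis=2)
        return xt.max(axis=2)

    def backward(self, grad: np.ndarray):
        shape_in, l_out = self._trim
        b, length, c = shape_in
        dxt = np.zeros((b, l_out, self.width, c), dtype=np.float32)
        np.put_along_axis(dxt, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(shape_in, dtype=np.float32)
        dx[:, : l_out * self.width, :] = dxt.reshape(b, l_out * self.width, c)
        return dx

    def step(self, lr, scale):
        pass


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.n_params = 0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        if rng is None or self.rate == 0.0:   # inference: identity
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray):
        return grad * self._mask

    def step(self, lr, scale):
        pass


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = rng.uniform(-limit, limit, (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def step(self, lr: float, scale: float):
        self.w -= lr * scale * self.dw
        self.b -= lr * scale * self.db


class CapnoCNN:
    """The three-block 1-D CNN with a 2-output dense head."""

    def __init__(self, config: NetworkConfig):
        config.layer_lengths()  # validates the shape algebra
        self.config = config
        rng = np.random.Generator(np.random.PCG64(config.seed))
        f1, f2, f3 = config.filters
        k = config.kernel
        self.conv1 = _Conv1D(1, f1, k, rng)
        self.pool1 = _MaxPool1D(config.pool)
        self.drop1 = _Dropout(config.dropout)
        self.conv2 = _Conv1D(f1, f2, k, rng)
        self.pool2 = _MaxPool1D(config.pool)
        self.drop2 = _Dropout(config.dropout)
        self.conv3 = _Conv1D(f2, f3, k, rng)
        self.pool3 = _MaxPool1D(config.pool)
        self.drop3 = _Dropout(config.dropout)
        self.dense = _Dense(config.flatten_width, 2, rng)
        self.trained = False

    # layer registry: (name, layer) in forward order
    def layers(self):
        return [
            ("C1", self.conv1), ("P1", self.pool1), ("D1", self.drop1),
            ("C2", self.conv2), ("P2", self.pool2), ("D2", self.drop2),
            ("C3", self.conv3), ("P3", self.pool3), ("D3", self.drop3),
            ("F1", None), ("F2", self.dense),
        ]

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """x: (B, input_length) float32; rng enables dropout (training mode)."""
        h = x[:, :, None].astype(np.float32)
        for block in (
            (self.conv1, self.pool1, self.drop1),
            (self.conv2, self.pool2, self.drop2),
            (self.conv3, self.pool3, self.drop3),
        ):
            conv, pool, drop = block
            h = drop.forward(pool.forward(conv.forward(h)), rng)
        self._flat_shape = h.shape
        return self.dense.forward(h.reshape(h.shape[0], -1))

    def backward(self, grad: np.ndarray):
        g = self.dense.backward(grad).reshape(self._flat_shape)
        for conv, pool, drop in (
            (self.conv3, self.pool3, self.drop3),
            (self.conv2, self.pool2, self.drop2),
            (self.conv1, self.pool1, self.drop1),
        ):
            g = drop.backward(g) if hasattr(drop, "_mask") else g
            g = conv.backward(pool.backward(g))
        return g

    def _param_layers(self):
        return [self.conv1, self.conv2, self.conv3, self.dense]

    def grad_norm(self) -> float:
        total = 0.0
        for layer in self._param_layers():
            total += float((layer.dw ** 2).sum() + (layer.db ** 2).sum())
        return np.sqrt(total)

    def step(self, lr: float):
        clip = self.config.grad_clip
        norm = self.grad_norm()
        scale = 1.0 if norm <= clip else clip / norm
        for layer in self._param_layers():
            layer.step(lr, scale)


def build_network(config: NetworkConfig = NetworkConfig()) -> CapnoCNN:
    """Instantiate the network, validating the layer shape algebra."""
    return CapnoCNN(config)


def count_parameters(network: CapnoCNN) -> dict[str, int]:
    """Trainable parameter count per layer, keyed by layer name.

    Conv layers count k * C_in * C_out + C_out; the dense head counts
    in * out + out; pooling, dropout and flatten hold no parameters.
    """
    counts = {}
    for name, layer in network.layers():
        counts[name] = 0 if layer is None else layer.n_params
    return counts


def train_network(
    network: CapnoCNN,
    sequences: np.ndarray,
    targets: np.ndarray,
    val_sequences: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
) -> dict:
    """Mini-batch SGD on mean squared error.

    Runs ``config.epochs`` epochs with per-epoch exponentially decayed
    learning rate.  Returns ``{"train_loss": [...], "val_loss": [...]}``
    (validation entries are NaN when no validation set is given).

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite, naming the epoch.
    """
    x = np.asarray(sequences, dtype=np.float32)
    y = np.asarray(targets, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != network.config.input_length:
        raise ValueError(
            f"sequences must be (n, {network.config.input_length}), got {x.shape}"
        )
    if x.shape[0] < 2:
        raise ValueError("training needs at least 2 subjects")
    cfg = network.config
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))
    if not network.trained:
        # start the output head at the target mean so SGD spends its
        # budget on signal, not on closing the DC offset in liters
        network.dense.b[:] = y.mean(axis=0).astype(np.float32)
    history = {"train_loss": [], "val_loss": []}
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * cfg.lr_decay ** epoch
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            pred = network.forward(xb, rng)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch
                )
            network.backward((2.0 / resid.size) * resid.astype(np.float32))
            network.step(lr)
            batch_losses.append(loss)
        history["train_loss"].append(float(np.mean(batch_losses)))
        if val_sequences is not None and val_targets is not None:
            vp = network.forward(np.asarray(val_sequences, dtype=np.float32))
            history["val_loss"].append(
                float(np.mean((vp - np.asarray(val_targets)) ** 2))
            )
        else:
            history["val_loss"].append(float("nan"))
    network.trained = True
    return history


def predict_sequence(network: CapnoCNN, sequences: np.ndarray) -> np.ndarray:
    """(n, 2) predictions of (FEV1, FVC) in liters, floored at 0.1 L.

    Dropout is disabled, so inference is deterministic.
    """
    if not network.trained:
        raise NotFittedError("network has not been trained")
    x = np.asarray(sequences, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != network.config.input_length:
        raise ValueError(
            f"sequences must be (n, {network.config.input_length}), got {x.shape}"
        )
    out = np.empty((x.shape[0], 2), dtype=float)
    for start in range(0, x.shape[0], 256):
        out[start: start + 256] = network.forward(x[start: start + 256])
    return np.maximum(out, PREDICTION_FLOOR)


def save_network(network: CapnoCNN, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar recording the configuration."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(network._param_layers()):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": asdict(network.config), "trained": network.trained}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: str | Path) -> CapnoCNN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    cfg["filters"] = tuple(cfg["filters"])
    network = CapnoCNN(NetworkConfig(**cfg))
    data = np.load(path.with_suffix(".npz"))
    for i, layer in enumerate(network._param_layers()):
        layer.w = data[f"w{i}"].astype(np.float32)
        layer.b = data[f"b{i}"].astype(np.float32)
    network.trained = bool(sidecar["trained"])
    return network
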