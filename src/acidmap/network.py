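"""Lightweight 1-D convolutional calibration network (pure numpy).

The network maps a preprocessed 256-point spectrum to a pH estimate and a
chip-group distribution, letting one model calibrate across chips by
recognizing each chip's spectral signature. The fixed layer inventory is
six convolutions, three pooling, three batch-normalization and three
dropout layers, and two fully connected layers, arranged as three blocks of

    BN -> conv(k) -> ReLU -> conv(k) -> ReLU -> pool(2) -> dropout

followed by FC -> ReLU -> FC(1 + n_groups). Training minimizes
``MSE(pH) + lambda * cross-entropy(group)`` with Adam. Everything runs in
float32 on a single thread, so a fixed seed reproduces training bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import NetworkSpecError, TrainingError
from .io import CHIP_GROUPS, SpectraDataset

F32 = np.float32


# ---------------------------------------------------------------------------
# split protocol

def stratified_split_indices(keys, train_frac: float = 0.8, seed: int = 0) -> np.ndarray:
    """Boolean train mask with |train| = round(train_frac * N), stratified.

    ``keys`` is a sequence of hashable stratum labels (one per sample);
    every stratum contributes to both sides where its size allows. The
    global train count is exact (largest-remainder allocation over strata).
    """
    keys = list(keys)
    n = len(keys)
    if n < 2:
        raise ValueError("need at least two samples to split")
    n_train = int(np.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(seed)

    cells: dict = {}
    for i, k in enumerate(keys):
        cells.setdefault(k, []).append(i)
    ordered = sorted(cells.items(), key=lambda kv: repr(kv[0]))

    base = [int(np.floor(train_frac * len(idx))) for _, idx in ordered]
    rem = [train_frac * len(idx) - b for (_, idx), b in zip(ordered, base)]
    extras = n_train - sum(base)
    for j in sorted(range(len(ordered)), key=lambda j: (-rem[j], j)):
        if extras <= 0:
            break
        if base[j] < len(ordered[j][1]):
            base[j] += 1
            extras -= 1
    # pathological leftovers (tiny strata): hand out wherever room remains
    for j in range(len(ordered)):
        if extras <= 0:
            break
        room = len(ordered[j][1]) - base[j]
        take = min(room, extras)
        base[j] += take
        extras -= take

    mask = np.zeros(n, dtype=bool)
    for (_, idx), b in zip(ordered, base):
        perm = rng.permutation(len(idx))
        for p in perm[:b]:
            mask[idx[p]] = True
    return mask


def split_dataset(
    dataset: SpectraDataset, train_frac: float = 0.8, seed: int = 0
) -> SpectraDataset:
    """Assign a stratified train/test split (by chip and nominal pH) in place."""
    keys = list(zip(dataset.table["chip_id"], dataset.table["nominal_ph"]))
    mask = stratified_split_indices(keys, train_frac=train_frac, seed=seed)
    dataset.table["split"] = np.where(mask, "train", "test")
    return dataset


# ---------------------------------------------------------------------------
# layers

class _Conv1d:
    kind = "conv"

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k, self.c_in, self.pad = k, c_in, k // 2
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in * k)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)

    def forward(self, x, train):
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (n, c, L, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * length, c * self.k)
        out = cols @ self.W.T + self.b
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.reshape(n, length, -1).transpose(0, 2, 1))

    def backward(self, dout):
        cols, (n, c, length) = self._cache
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(n * length, -1)
        self.dW = (d2.T @ cols).astype(F32)
        self.db = d2.sum(axis=0).astype(F32)
        dcols = (d2 @ self.W).reshape(n, length, c, self.k)
        dxp = np.zeros((n, c, length + 2 * self.pad), dtype=F32)
        for j in range(self.k):
            dxp[:, :, j : j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, self.pad : self.pad + length]

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm1d:
    kind = "bn"

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._cache = (xhat, inv, x.shape) if train else None
        return (self.gamma[:, None] * xhat + self.beta[:, None]).astype(F32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2]
        self.dgamma = (dout * xhat).sum(axis=(0, 2)).astype(F32)
        self.dbeta = dout.sum(axis=(0, 2)).astype(F32)
        dxhat = dout * self.gamma[:, None]
        dx = (inv[:, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        return dx.astype(F32)

    def params(self):
        return [("gamma", self), ("beta", self)]


class _AvgPool1d:
    kind = "pool"

    def __init__(self, width: int = 2):
        self.width = width

    def forward(self, x, train):
        n, c, length = x.shape
        self._shape = x.shape
        return x.reshape(n, c, length // self.width, self.width).mean(axis=3)

    def backward(self, dout):
        n, c, length = self._shape
        return np.repeat(dout / self.width, self.width, axis=2).astype(F32)

    def params(self):
        return []


class _MaxPool1d:
    kind = "pool"

    def __init__(self, width: int = 2):
        self.width = width

    def forward(self, x, train):
        n, c, length = x.shape
        xr = x.reshape(n, c, length // self.width, self.width)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dout):
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // self.width, self.width), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=3)
        return dxr.reshape(n, c, length)

    def params(self):
        return []


class _Dropout:
    kind = "dropout"

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class _ReLU:
    kind = "relu"

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    kind = "flatten"

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    kind = "fc"

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(F32)
        self.b = np.zeros(d_out, dtype=F32)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = (self._x.T @ dout).astype(F32)
        self.db = dout.sum(axis=0).astype(F32)
        return (dout @ self.W.T).astype(F32)

    def params(self):
        return [("W", self), ("b", self)]


# ---------------------------------------------------------------------------
# network

@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the calibration network.

    ``channels`` must have exactly three entries: the fixed layer inventory
    (6 conv / 3 pool / 3 BN / 3 dropout / 2 FC) dictates three conv blocks.
    """

    input_len: int = 256
    channels: tuple[int, int, int] = (8, 16, 32)
    kernel: int = 5
    pool: int = 2
    #: the default study is noise-limited, not overfit-limited (train and
    #: test errors match), so the dropout rate defaults to zero; the three
    #: dropout layers stay in the graph and the rate is configurable
    dropout: float = 0.0
    fc_width: int = 64
    n_groups: int = len(CHIP_GROUPS)
    learning_rate: float = 3e-3
    epochs: int = 150
    batch_size: int = 256
    lambda_cls: float = 0.5
    #: "avg" preserves band amplitudes linearly (this is an amplitude-
    #: precision regression); "max" is the conventional alternative
    pool_type: str = "avg"
    #: step decay: multiply the rate by lr_decay_factor at these epoch fractions
    lr_decay_at: tuple[float, float] = (0.6, 0.85)
    lr_decay_factor: float = 0.3

    def validate(self) -> None:
        if len(self.channels) != 3:
            raise NetworkSpecError("exactly three conv blocks are required")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise NetworkSpecError("kernel size must be odd and positive")
        if self.input_len % self.pool**3 != 0:
            raise NetworkSpecError("input length must survive three pooling stages")
        if not 0.0 <= self.dropout < 1.0:
            raise NetworkSpecError("dropout must be in [0, 1)")
        if self.pool_type not in ("avg", "max"):
            raise NetworkSpecError("pool_type must be 'avg' or 'max'")


class CNNCalibrator:
    """Multi-output 1-D CNN: one pH scalar plus chip-group logits."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.init_seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC4,)))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(0xD0,))
        )
        layers: list = []
        c_prev, length = 1, spec.input_len
        for c in spec.channels:
            layers.append(_BatchNorm1d(c_prev))
            layers.append(_Conv1d(c_prev, c, spec.kernel, rng))
            layers.append(_ReLU())
            layers.append(_Conv1d(c, c, spec.kernel, rng))
            layers.append(_ReLU())
            pool_cls = _AvgPool1d if spec.pool_type == "avg" else _MaxPool1d
            layers.append(pool_cls(spec.pool))
            layers.append(_Dropout(spec.dropout, self._dropout_rng))
            c_prev = c
            length //= spec.pool
        layers.append(_Flatten())
        layers.append(_Dense(c_prev * length, spec.fc_width, rng))
        layers.append(_ReLU())
        layers.append(_Dense(spec.fc_width, 1 + spec.n_groups, rng))
        self.layers = layers
        self.history: list[dict] = []
        self.train_seed: int | None = None

    # -- plumbing ----------------------------------------------------------
    def layer_counts(self) -> dict[str, int]:
        """Audit of the architecture against the fixed inventory."""
        counts: dict[str, int] = {}
        for lay in self.layers:
            counts[lay.kind] = counts.get(lay.kind, 0) + 1
        return counts

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[-1] != self.spec.input_len:
            raise NetworkSpecError(
                f"input length {x.shape[-1]} != spec length {self.spec.input_len}"
            )
        out = x.astype(F32)
        for lay in self.layers:
            out = lay.forward(out, train)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)

    def parameters(self):
        for lay in self.layers:
            for name, owner in lay.params():
                yield name, owner

    def predict(self, x: np.ndarray, batch: int = 2048) -> tuple[np.ndarray, np.ndarray]:
        """pH estimates and chip-group probability rows (softmax, sum to 1)."""
        x = np.asarray(x, dtype=F32)
        phs, probs = [], []
        for i in range(0, x.shape[0], batch):
            out = self.forward(x[i : i + batch], train=False)
            phs.append(out[:, 0].astype(float))
            probs.append(_softmax(out[:, 1:]).astype(float))
        return np.concatenate(phs), np.concatenate(probs)

    def predict_ph(self, x: np.ndarray) -> np.ndarray:
        return self.predict(x)[0]


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> CNNCalibrator:
    """Instantiate an untrained calibration network from a spec."""
    return CNNCalibrator(spec or NetworkSpec(), seed=seed)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def encode_groups(groups) -> np.ndarray:
    idx = {g: i for i, g in enumerate(CHIP_GROUPS)}
    return np.array([idx[g] for g in groups], dtype=np.int64)


def train(
    model: CNNCalibrator,
    x: np.ndarray,
    y_ph: np.ndarray,
    y_group: np.ndarray,
    seed: int = 0,
    epochs: int | None = None,
) -> CNNCalibrator:
    """Train with Adam on ``MSE(pH) + lambda * cross-entropy(group)``.

    ``y_ph`` are pH-meter tags in raw pH units; ``y_group`` integer group
    indices. Per-epoch mean losses are recorded in ``model.history``.
    Deterministic under a fixed seed (single-threaded numpy).
    """
    spec = model.spec
    epochs = spec.epochs if epochs is None else epochs
    x = np.asarray(x, dtype=F32)
    y_ph = np.asarray(y_ph, dtype=F32)
    y_group = np.asarray(y_group, dtype=np.int64)
    n = x.shape[0]
    if n == 0:
        raise TrainingError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x7A,)))
    adam = _Adam(model, spec.learning_rate)
    model.train_seed = seed
    eye = np.eye(spec.n_groups, dtype=F32)

    for epoch in range(epochs):
        frac = epoch / max(epochs, 1)
        adam.lr = spec.learning_rate
        for cut in spec.lr_decay_at:
            if frac >= cut:
                adam.lr *= spec.lr_decay_factor
        perm = rng.permutation(n)
        tot_ph = tot_ce = 0.0
        for start in range(0, n, spec.batch_size):
            sel = perm[start : start + spec.batch_size]
            out = model.forward(x[sel], train=True)
            m = sel.size
            resid = out[:, 0] - y_ph[sel]
            probs = _softmax(out[:, 1:])
            onehot = eye[y_group[sel]]
            ph_loss = float(np.mean(resid**2))
            ce = float(-np.mean(np.log(probs[np.arange(m), y_group[sel]] + 1e-12)))
            if not np.isfinite(ph_loss) or not np.isfinite(ce):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            dout = np.empty((m, 1 + spec.n_groups), dtype=F32)
            dout[:, 0] = 2.0 * resid / m
            dout[:, 1:] = spec.lambda_cls * (probs - onehot) / m
            model.backward(dout)
            adam.step()
            tot_ph += ph_loss * m
            tot_ce += ce * m
        model.history.append(
            {"epoch": epoch, "ph_mse": tot_ph / n, "group_ce": tot_ce / n,
             "loss": tot_ph / n + spec.lambda_cls * tot_ce / n}
        )
    _recalibrate_batchnorm(model, x, rng)
    return model


def _recalibrate_batchnorm(
    model: CNNCalibrator, x: np.ndarray, rng: np.random.Generator, passes: int = 50
) -> None:
    """Re-estimate BN running statistics with dropout disabled.

    Dropout feeds the next block's batch-normalization during training, so
    the running statistics accumulated there describe a thinned activation
    distribution, not the one seen at inference. A short stats-only sweep
    over the training data with dropout off closes that train/eval gap.
    """
    dropouts = [lay for lay in model.layers if lay.kind == "dropout"]
    saved = [lay.p for lay in dropouts]
    for lay in dropouts:
        lay.p = 0.0
    batch = min(model.spec.batch_size, x.shape[0])
    for _ in range(passes):
        sel = rng.integers(0, x.shape[0], batch)
        model.forward(x[sel], train=True)
    for lay, p in zip(dropouts, saved):
        lay.p = p


def save_model(model: CNNCalibrator, directory: str) -> None:
    """Persist a trained model: spec JSON, weights blob, history CSV."""
    import json
    import os

    from dataclasses import asdict

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "spec.json"), "w") as fh:
        json.dump(
            {"spec": asdict(model.spec), "init_seed": model.init_seed,
             "train_seed": model.train_seed},
            fh, indent=1,
        )
    arrays = {}
    for i, lay in enumerate(model.layers):
        for name, owner in lay.params():
            arrays[f"{i}_{name}"] = getattr(owner, name)
        if lay.kind == "bn":
            arrays[f"{i}_running_mean"] = lay.running_mean
            arrays[f"{i}_running_var"] = lay.running_var
    np.savez(os.path.join(directory, "weights.npz"), **arrays)
    with open(os.path.join(directory, "history.csv"), "w") as fh:
        fh.write("epoch,ph_mse,group_ce,loss\n")
        for row in model.history:
            fh.write(f"{row['epoch']},{row['ph_mse']:.6g},"
                     f"{row['group_ce']:.6g},{row['loss']:.6g}\n")


def load_model(directory: str) -> CNNCalibrator:
    """Restore a model written by :func:`save_model`."""
    import json
    import os

    with open(os.path.join(directory, "spec.json")) as fh:
        doc = json.load(fh)
    doc["spec"]["channels"] = tuple(doc["spec"]["channels"])
    model = CNNCalibrator(NetworkSpec(**doc["spec"]), seed=doc["init_seed"])
    model.train_seed = doc["train_seed"]
    blob = np.load(os.path.join(directory, "weights.npz"))
    for i, lay in enumerate(model.layers):
        for name, owner in lay.params():
            setattr(owner, name, blob[f"{i}_{name}"])
        if lay.kind == "bn":
            lay.running_mean = blob[f"{i}_running_mean"]
            lay.running_var = blob[f"{i}_running_var"]
    return model


class _Adam:
    def __init__(self, model: CNNCalibrator, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.entries = list(model.parameters())
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(getattr(o, n)) for n, o in self.entries]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (name, owner) in enumerate(self.entries):
            g = getattr(owner, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[i] / b1t)
                      / (np.sqrt(self.v[i] / b2t) + self.eps))
            param = getattr(owner, name)
            param -= update.astype(param.dtype)
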