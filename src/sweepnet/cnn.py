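"""CNN classifier for SNP-window images, implemented in NumPy.

The default architecture follows the published design for this task:
three combined layers (a 2D convolution paired with a max-pooling layer),
32 filters per convolution, one dense layer of size 32 and a 2-way
softmax output ("neutral" vs "selection").  The search space around it —
2-5 combined layers, filter sizes 8/16/32/64 in increasing, decreasing or
constant form, 1-2 dense layers of size 16/32/64 — is expressible through
:class:`ArchSpec`.

Training uses softmax cross-entropy with the Adam optimizer and keeps the
weights from the epoch with the highest validation accuracy (ties broken
toward the earliest epoch).  All randomness (weight init, validation
split, batch shuffling) derives from a single seed, so training curves
are reproducible on one device; inference is deterministic.

Everything runs in float32.  Convolutions are 'same'-padded and computed
as im2col matrix products, which keeps training of the default network on
tens of thousands of 20x50 images within a few minutes on one CPU core.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .windows import GRAY_MAX

__all__ = [
    "ArchSpec",
    "TrainedModel",
    "ProbMatrix",
    "build_model",
    "train",
    "infer",
    "save_model",
    "load_model",
]

PUBLISHED_COMBINED_LAYERS = (2, 3, 4, 5)
PUBLISHED_FILTER_SIZES = (8, 16, 32, 64)
PUBLISHED_DENSE_SIZES = (16, 32, 64)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchSpec:
    """Hyper-parameters of the window-classification network."""

    filters: tuple[int, ...] = (32, 32, 32)
    dense_sizes: tuple[int, ...] = (32,)
    n_classes: int = 2
    kernel: int = 3
    pool: int = 2

    def __post_init__(self):
        if len(self.filters) == 0:
            raise ValueError("at least one combined layer is required")
        if any(f < 1 for f in self.filters):
            raise ValueError("filter counts must be positive")
        if any(d < 1 for d in self.dense_sizes):
            raise ValueError("dense sizes must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.pool < 1:
            raise ValueError("pool must be >= 1")
        if len(self.filters) not in PUBLISHED_COMBINED_LAYERS:
            import warnings

            warnings.warn(
                f"{len(self.filters)} combined layers is outside the "
                f"published search space {PUBLISHED_COMBINED_LAYERS}"
            )

    @property
    def n_combined_layers(self) -> int:
        return len(self.filters)

    @classmethod
    def from_search(
        cls,
        n_combined_layers: int = 3,
        filter_size: int = 32,
        form: str = "constant",
        n_dense: int = 1,
        dense_size: int = 32,
        n_classes: int = 2,
    ) -> "ArchSpec":
        """Build a spec from the hyper-parameter search vocabulary:
        number of combined layers, filter size and form
        (increasing/decreasing/constant), number and size of dense
        layers."""
        sizes = sorted(PUBLISHED_FILTER_SIZES)
        if form == "constant":
            filters = (filter_size,) * n_combined_layers
        else:
            if filter_size not in sizes:
                raise ValueError(
                    f"filter_size {filter_size} not in {sizes} for "
                    f"form={form!r}"
                )
            start = sizes.index(filter_size)
            idx = [min(start + i, len(sizes) - 1) for i in range(n_combined_layers)]
            ladder = tuple(sizes[i] for i in idx)
            filters = ladder if form == "increasing" else tuple(reversed(ladder))
            if form not in ("increasing", "decreasing"):
                raise ValueError("form must be increasing/decreasing/constant")
        return cls(
            filters=filters,
            dense_sizes=(dense_size,) * n_dense,
            n_classes=n_classes,
        )


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv2D:
    """'same'-padded 2D convolution with ReLU.

    Data layout is channels-last (B, H, W, C); the convolution is
    computed as k*k shifted (C x O) tensor contractions, which keeps the
    matrix products BLAS-friendly without a full im2col copy.
    """

    def __init__(self, c_in, c_out, kernel, rng):
        k = kernel
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x):
        B, H, W, C = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        v = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,H,W,C,k,k
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(B * H * W, k * k * C)

    def forward(self, x, train):
        B, H, W, C = x.shape
        o = self.w.shape[-1]
        cols = self._im2col(x)
        y = cols @ self.w.reshape(-1, o)
        y += self.b
        relu_mask = y > 0
        y *= relu_mask
        y = y.reshape(B, H, W, o)
        if train:
            self._cache = (cols, relu_mask, x.shape)
        return y

    def backward(self, dy):
        cols, relu_mask, x_shape = self._cache
        B, H, W, C = x_shape
        k, pad, o = self.k, self.k // 2, self.w.shape[-1]
        dy2 = dy.reshape(B * H * W, o) * relu_mask
        self.dw = (cols.T @ dy2).reshape(self.w.shape)
        self.db = dy2.sum(axis=0)
        dcols = (dy2 @ self.w.reshape(-1, o).T).reshape(B, H, W, k, k, C)
        dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
        self._cache = None
        return dxp[:, pad:pad + H, pad:pad + W, :]

    def grads(self):
        return [self.dw, self.db]


class _MaxPool2D:
    """Non-overlapping max pooling (channels-last); trailing rows/columns
    that do not fill a complete pool cell are dropped.  On ties within a
    pool cell the gradient is split evenly among the tied entries."""

    def __init__(self, pool):
        self.p = pool

    def params(self):
        return []

    def out_shape(self, h, w):
        return h // self.p, w // self.p

    def forward(self, x, train):
        p = self.p
        B, H, W, C = x.shape
        Hp, Wp = H // p, W // p
        xr = x[:, : Hp * p, : Wp * p, :].reshape(B, Hp, p, Wp, p, C)
        y = xr.max(axis=(2, 4))
        if train:
            self._cache = (xr, y, x.shape)
        return y

    def backward(self, dy):
        xr, y, x_shape = self._cache
        p = self.p
        B, Hp, _, Wp, _, C = xr.shape
        mask = (xr == y[:, :, None, :, None, :]).astype(np.float32)
        counts = mask.sum(axis=(2, 4))
        scaled = (dy / counts)[:, :, None, :, None, :]
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, : Hp * p, : Wp * p, :] = (mask * scaled).reshape(
            B, Hp * p, Wp * p, C
        )
        self._cache = None
        return dx

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng, relu=True):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        y = x @ self.w + self.b
        mask = None
        if self.relu:
            mask = y > 0
            y = np.where(mask, y, 0.0).astype(np.float32, copy=False)
        if train:
            self._cache = (x, mask)
        return y

    def backward(self, dy):
        x, mask = self._cache
        if mask is not None:
            dy = np.where(mask, dy, 0.0)
        self.dw = x.T @ dy
        self.db = dy.sum(axis=0)
        self._cache = None
        return dy @ self.w.T

    def grads(self):
        return [self.dw, self.db]


class CNN:
    """The assembled network.  Input: ``B x N x W`` images in [0, 1]."""

    def __init__(self, spec: ArchSpec, input_shape: tuple[int, int], seed: int = 0):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        h, w = input_shape
        if h < 1 or w < 1:
            raise ValueError("input dimensions must be >= 1")
        self.layers = []
        c = 1
        for li, f in enumerate(spec.filters):
            self.layers.append(_Conv2D(c, f, spec.kernel, rng))
            pool = _MaxPool2D(spec.pool)
            h2, w2 = pool.out_shape(h, w)
            if h2 < 1 or w2 < 1:
                raise ValueError(
                    f"combined layer {li + 1}: pooling reduces the feature "
                    f"map from {h}x{w} below 1 pixel"
                )
            self.layers.append(pool)
            h, w, c = h2, w2, f
        self.flat_dim = c * h * w
        n_in = self.flat_dim
        for d in spec.dense_sizes:
            self.layers.append(_Dense(n_in, d, rng, relu=True))
            n_in = d
        self.layers.append(_Dense(n_in, spec.n_classes, rng, relu=False))

    # ------------------------------------------------------------------
    def forward(self, x, train=False):
        """Logits for a batch of images (values already scaled to [0,1])."""
        z = np.ascontiguousarray(x[:, :, :, None], dtype=np.float32)
        flat_done = False
        for layer in self.layers:
            if isinstance(layer, _Dense) and not flat_done:
                self._fold_shape = z.shape
                z = z.reshape(z.shape[0], -1)
                flat_done = True
            z = layer.forward(z, train)
        return z

    def backward(self, dlogits):
        dz = dlogits
        for layer in reversed(self.layers):
            if not isinstance(layer, _Dense) and dz.ndim == 2:
                dz = dz.reshape(self._fold_shape)  # undo the flatten
            dz = layer.backward(dz)
        return dz

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(params) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w


def build_model(spec: ArchSpec, input_shape: tuple[int, int], seed: int = 0) -> CNN:
    """Instantiate an untrained network for ``input_shape = (N, W)``
    images (samples x SNPs)."""
    return CNN(spec, input_shape, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """A trained network: architecture, weights, and training metadata."""

    architecture: ArchSpec
    input_shape: tuple[int, int]
    weights: list
    class_labels: tuple[str, ...] = ("neutral", "selection")
    meta: dict = field(default_factory=dict)

    def network(self) -> CNN:
        cached = getattr(self, "_net", None)
        if cached is None:
            cached = CNN(self.architecture, self.input_shape, seed=0)
            cached.set_weights(self.weights)
            self._net = cached
        return cached


@dataclass
class ProbMatrix:
    """``c x L`` posterior class probabilities, one column per window."""

    values: np.ndarray
    class_labels: tuple[str, ...]
    window_centers_bp: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be c x L")
        if self.values.size and not np.allclose(
            self.values.sum(axis=0), 1.0, atol=1e-6
        ):
            raise ValueError("probability columns must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def class_row(self, label: str) -> np.ndarray:
        return self.values[self.class_labels.index(label)]


def _scale_images(images) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim != 3:
        raise ValueError("images must be L x N x W")
    x = x.astype(np.float32)
    if x.size and x.max() > 1.0:
        x = x / np.float32(GRAY_MAX)
    return x


def train(
    model: CNN,
    images,
    labels,
    epochs: int = 6,
    val_fraction: float = 0.1,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    seed: int = 0,
    class_labels: tuple[str, ...] = ("neutral", "selection"),
    verbose: bool = False,
) -> TrainedModel:
    """Train with checkpoint-on-validation-accuracy.

    After every epoch the validation accuracy is recorded; the returned
    weights are those of the epoch with the maximum validation accuracy
    (earliest epoch on ties).  ``labels`` are integer class indices into
    ``class_labels``.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    x = _scale_images(images)
    y = np.asarray(labels, dtype=np.int64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("images/labels length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if classes.size != len(class_labels):
        class_labels = tuple(str(c) for c in classes) if len(
            class_labels
        ) != classes.size else class_labels

    rng = np.random.default_rng(seed)
    # stratified validation split
    val_idx = []
    train_idx = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    val_idx = np.concatenate(val_idx)
    train_idx = np.concatenate(train_idx)
    if train_idx.size == 0:
        raise ValueError("validation split leaves no training data")

    opt = _Adam(model.params(), lr=learning_rate)
    history = []
    best_acc, best_epoch, best_weights = -1.0, -1, model.get_weights()
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        for i in range(0, order.size, batch_size):
            bi = order[i:i + batch_size]
            logits = model.forward(x[bi], train=True)
            probs = _softmax(logits)
            dlogits = probs
            dlogits[np.arange(bi.size), y[bi]] -= 1.0
            dlogits /= np.float32(bi.size)
            model.backward(dlogits.astype(np.float32))
            opt.step(model.params(), model.grads())
        val_pred = _predict_classes(model, x[val_idx])
        acc = float((val_pred == y[val_idx]).mean())
        history.append(acc)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: val_acc={acc:.4f}")
        if acc > best_acc:  # strict > keeps the earliest epoch on ties
            best_acc, best_epoch = acc, epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(
        architecture=model.spec,
        input_shape=model.input_shape,
        weights=best_weights,
        class_labels=tuple(class_labels),
        meta={
            "epochs": epochs,
            "val_accuracy_history": history,
            "best_val_accuracy": best_acc,
            "best_epoch": best_epoch,
            "seed": seed,
            "batch_size": batch_size,
            "learning_rate": learning_rate,
            "n_train": int(train_idx.size),
            "n_val": int(val_idx.size),
        },
    )


def _predict_classes(net: CNN, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    out = np.empty(x.shape[0], dtype=np.int64)
    for i in range(0, x.shape[0], batch_size):
        out[i:i + batch_size] = net.forward(x[i:i + batch_size]).argmax(axis=1)
    return out


def infer(model: TrainedModel, images, window_centers_bp=None,
          batch_size: int = 512) -> ProbMatrix:
    """Posterior class probabilities for a stack of window images.

    Column ``j`` of the result holds the class posteriors of window
    ``j``; inference is deterministic for fixed weights.
    """
    x = _scale_images(images)
    if x.shape[0] and x.shape[1:] != tuple(model.input_shape):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match the model's "
            f"training shape {tuple(model.input_shape)}"
        )
    net = model.network()
    probs = np.empty((x.shape[0], model.architecture.n_classes), dtype=np.float64)
    for i in range(0, x.shape[0], batch_size):
        probs[i:i + batch_size] = _softmax(
            net.forward(x[i:i + batch_size]).astype(np.float64)
        )
    return ProbMatrix(
        values=probs.T,
        class_labels=model.class_labels,
        window_centers_bp=(
            None if window_centers_bp is None
            else np.asarray(window_centers_bp, dtype=float)
        ),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory) -> None:
    """Write a model bundle: ``weights.npz`` plus ``meta.json``."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(
        d / "weights.npz",
        **{f"w{i}": w for i, w in enumerate(model.weights)},
    )
    meta = {
        "architecture": asdict(model.architecture),
        "input_shape": list(model.input_shape),
        "class_labels": list(model.class_labels),
        "meta": model.meta,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_model(directory) -> TrainedModel:
    d = pathlib.Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    arch = meta["architecture"]
    spec = ArchSpec(
        filters=tuple(arch["filters"]),
        dense_sizes=tuple(arch["dense_sizes"]),
        n_classes=arch["n_classes"],
        kernel=arch["kernel"],
        pool=arch["pool"],
    )
    with np.load(d / "weights.npz") as z:
        weights = [z[f"w{i}"] for i in range(len(z.files))]
    return TrainedModel(
        architecture=spec,
        input_shape=tuple(meta["input_shape"]),
        weights=weights,
        class_labels=tuple(meta["class_labels"]),
        meta=meta["meta"],
    )
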