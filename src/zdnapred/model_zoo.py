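"""Architecture grammar, grid enumeration and training.

Models are per-nucleotide segmenters: a length-L multi-channel input
yields a length-L vector of Z-DNA probabilities. The grammar composes an
optional convolutional block (1-2 stride-1 same-padding layers, ReLU in
between), an optional recurrent block (1-2 stacked, optionally
bidirectional LSTMs), and exactly one final dense block (per-position
fully connected layers with dropout 0.5 in between) ending in two output
units whose softmax gives the class probabilities; the reported
probability is the Z class unit. Hybrids run convolution before
recurrence. Training uses RMSprop on per-nucleotide cross-entropy with
minibatches of windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product

import numpy as np

from . import _nn
from .dataset import Window, WindowSet
from .features import FeatureMatrix
from .sparse_store import SparseTrack

__all__ = [
    "ConvBlock",
    "RecurrentBlock",
    "DenseBlock",
    "ModelSpec",
    "TrainOptions",
    "TrainedModel",
    "TrainingDiverged",
    "enumerate_grid",
    "receptive_field",
    "build_network",
    "train",
    "predict",
    "save_model",
    "load_model",
    "BEST_RNN_SPEC",
    "BEST_CNN_SPEC",
    "INTERPRETATION_CNN_SPEC",
]


@dataclass(frozen=True)
class ConvBlock:
    n_layers: int = 1
    n_kernels: int = 8
    kernel_size: int = 5
    channel_pool: bool = False

    def __post_init__(self):
        if self.n_layers not in (1, 2):
            raise ValueError("conv block supports 1 or 2 layers")
        if not 1 <= self.n_kernels <= 17:
            raise ValueError("n_kernels must be in 1..17")
        if not (1 <= self.kernel_size <= 17 and self.kernel_size % 2 == 1):
            raise ValueError("kernel_size must be odd and in 1..17")


@dataclass(frozen=True)
class RecurrentBlock:
    n_layers: int = 1
    hidden_size: int = 32
    bidirectional: bool = True

    def __post_init__(self):
        if self.n_layers not in (1, 2):
            raise ValueError("recurrent block supports 1 or 2 layers")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be positive")


@dataclass(frozen=True)
class DenseBlock:
    n_layers: int = 1
    hidden_size: int = 32
    dropout: float = 0.5

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("dense block needs >= 1 layer")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered block list; validated against the grammar."""

    blocks: tuple

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        dense = [b for b in self.blocks if isinstance(b, DenseBlock)]
        if len(dense) != 1 or not isinstance(self.blocks[-1], DenseBlock):
            raise ValueError("exactly one dense block, placed last")
        conv = [i for i, b in enumerate(self.blocks) if isinstance(b, ConvBlock)]
        rec = [i for i, b in enumerate(self.blocks) if isinstance(b, RecurrentBlock)]
        if len(conv) > 1 or len(rec) > 1:
            raise ValueError("at most one conv and one recurrent block")
        if conv and rec and conv[0] > rec[0]:
            raise ValueError("hybrid order is conv -> recurrent -> dense")

    @property
    def kind(self) -> str:
        has_c = any(isinstance(b, ConvBlock) for b in self.blocks)
        has_r = any(isinstance(b, RecurrentBlock) for b in self.blocks)
        if has_c and has_r:
            return "hybrid"
        return "cnn" if has_c else ("rnn" if has_r else "dense")

    def to_dict(self) -> dict:
        kinds = {ConvBlock: "conv", RecurrentBlock: "recurrent", DenseBlock: "dense"}
        return {
            "blocks": [
                {"type": kinds[type(b)], **asdict(b)} for b in self.blocks
            ]
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelSpec":
        types = {"conv": ConvBlock, "recurrent": RecurrentBlock, "dense": DenseBlock}
        blocks = []
        for b in doc["blocks"]:
            b = dict(b)
            blocks.append(types[b.pop("type")](**b))
        return cls(tuple(blocks))


# Reference architectures, expressible in the grammar:
# best RNN (two bidirectional LSTMs, two dense layers with dropouts),
# best CNN (one conv layer with 3 kernels, one dense layer), and the
# two-layer kernel-5 CNN used for interpretation (receptive field 9).
BEST_RNN_SPEC = ModelSpec(
    (RecurrentBlock(n_layers=2, hidden_size=64, bidirectional=True), DenseBlock(n_layers=2))
)
BEST_CNN_SPEC = ModelSpec(
    (ConvBlock(n_layers=1, n_kernels=3, kernel_size=5), DenseBlock(n_layers=1))
)
INTERPRETATION_CNN_SPEC = ModelSpec(
    (ConvBlock(n_layers=2, n_kernels=8, kernel_size=5), DenseBlock(n_layers=1))
)


def receptive_field(spec: ModelSpec) -> int:
    """Input span (nt) fully determining one output, for CNN-only specs.

    For stride-1 stacks this is ``1 + sum(kernel_size - 1)`` over all
    convolutional layers; per-position dense layers add nothing. Recurrent
    blocks carry unbounded context, so the notion does not apply.
    """
    if any(isinstance(b, RecurrentBlock) for b in spec.blocks):
        raise ValueError("receptive field undefined for recurrent architectures")
    rf = 1
    for b in spec.blocks:
        if isinstance(b, ConvBlock):
            rf += b.n_layers * (b.kernel_size - 1)
    return rf


def enumerate_grid(grid_config: dict) -> list[ModelSpec]:
    """Deduplicated Cartesian product of hyperparameter candidates.

    ``grid_config`` maps family names (cnn, rnn, hybrid) to dicts of
    candidate lists: conv_layers, conv_kernels, kernel_sizes,
    recurrent_layers, hidden_sizes, bidirectional, dense_layers.
    """
    if not grid_config:
        raise ValueError("empty grid")
    specs: list[ModelSpec] = []
    seen = set()
    for family in sorted(grid_config):
        g = grid_config[family]
        dense_layers = g.get("dense_layers", [1])
        conv_axes = list(
            product(
                g.get("conv_layers", [1]),
                g.get("conv_kernels", [8]),
                g.get("kernel_sizes", [5]),
            )
        )
        rec_axes = list(
            product(
                g.get("recurrent_layers", [1]),
                g.get("hidden_sizes", [32, 64, 128]),
                g.get("bidirectional", [True, False]),
            )
        )
        if family == "cnn":
            combos = [((c, None, d)) for c, d in product(conv_axes, dense_layers)]
        elif family == "rnn":
            combos = [((None, r, d)) for r, d in product(rec_axes, dense_layers)]
        elif family == "hybrid":
            combos = [
                ((c, r, d)) for c, r, d in product(conv_axes, rec_axes, dense_layers)
            ]
        else:
            raise ValueError(f"unknown family {family!r}")
        for conv, rec, nd in combos:
            blocks = []
            if conv is not None:
                blocks.append(
                    ConvBlock(n_layers=conv[0], n_kernels=conv[1], kernel_size=conv[2])
                )
            if rec is not None:
                blocks.append(
                    RecurrentBlock(
                        n_layers=rec[0], hidden_size=rec[1], bidirectional=rec[2]
                    )
                )
            blocks.append(DenseBlock(n_layers=nd))
            spec = ModelSpec(tuple(blocks))
            if spec not in seen:
                seen.add(spec)
                specs.append(spec)
    if not specs:
        raise ValueError("empty grid")
    return specs


# -- network construction ----------------------------------------------


def build_network(spec: ModelSpec, in_channels: int, rng) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    prev = in_channels
    first_conv_done = False
    for block in spec.blocks:
        if isinstance(block, ConvBlock):
            for i in range(block.n_layers):
                group = "first_layer" if not first_conv_done else "other"
                layers.append(
                    _nn.Conv1d(prev, block.n_kernels, block.kernel_size, rng, group)
                )
                first_conv_done = True
                prev = block.n_kernels
                if i < block.n_layers - 1:
                    layers.append(_nn.ReLU())
            if block.channel_pool:
                layers.append(_nn.ChannelMaxPool())
                prev = 1
        elif isinstance(block, RecurrentBlock):
            for _ in range(block.n_layers):
                lstm = _nn.LSTM(prev, block.hidden_size, rng, block.bidirectional)
                layers.append(lstm)
                prev = lstm.out_channels
        elif isinstance(block, DenseBlock):
            for i in range(block.n_layers - 1):
                layers.append(_nn.Linear(prev, block.hidden_size, rng))
                layers.append(_nn.ReLU())
                layers.append(_nn.Dropout(block.dropout))
                prev = block.hidden_size
            layers.append(_nn.Linear(prev, 2, rng))
    return _nn.Sequential(layers)


@dataclass
class TrainOptions:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    rho: float = 0.9
    l1_first_layer: float = 0.0
    l1_other: float = 0.0
    early_stopping: bool = False
    patience: int = 5
    validation_fraction: float = 0.15
    channels: list[str] | None = None  # subset of feature channels to use


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainedModel:
    """A fitted per-nucleotide scorer bound to named feature channels."""

    spec: ModelSpec
    net: _nn.Sequential
    channel_names: list[str]
    training_log: list[dict]
    seed: int

    def predict_window(self, x: np.ndarray, both_classes: bool = False) -> np.ndarray:
        probs = _nn.softmax(self.net.forward(np.asarray(x, np.float64), train=False))
        return probs if both_classes else probs[1]

    def predict(self, fm: FeatureMatrix, start: int, end: int, chunk: int = 100_000):
        return predict(self, fm, start, end, chunk=chunk)

    def predict_track(self, store: dict[str, FeatureMatrix]) -> dict[str, np.ndarray]:
        return {c: self.predict(store[c], 0, store[c].length) for c in sorted(store)}


def _window_xy(
    w: Window,
    store: dict[str, FeatureMatrix],
    labels: dict[str, SparseTrack | np.ndarray],
    channels: list[str],
):
    x = store[w.chromosome].dense(w.start, w.end, channels)
    lab = labels[w.chromosome]
    if isinstance(lab, SparseTrack):
        y = lab.slice(w.start, w.end)
    else:
        y = np.asarray(lab)[w.start : w.end]
    return x, (y > 0).astype(np.int64)


def _f1_at_half(model_net, xs, ys) -> float:
    tp = fp = fn = 0
    for x, y in zip(xs, ys):
        pred = _nn.softmax(model_net.forward(x, train=False))[1] > 0.5
        tp += int(np.sum(pred & (y == 1)))
        fp += int(np.sum(pred & (y == 0)))
        fn += int(np.sum(~pred & (y == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def train(
    spec: ModelSpec,
    ws: WindowSet,
    store: dict[str, FeatureMatrix],
    labels: dict[str, SparseTrack | np.ndarray],
    opts: TrainOptions | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a model on the train split with RMSprop; fully seeded.

    Gradients are averaged over minibatches of whole windows. Optional L1
    penalties (applied proximally) act separately on the first layer and
    on the remaining parameters. Optional early stopping monitors F1 on a
    held-aside validation fraction of the training windows.
    """
    opts = opts or TrainOptions()
    windows = ws.train_windows()
    if not windows:
        raise ValueError("empty train split")
    any_fm = next(iter(store.values()))
    channels = list(opts.channels) if opts.channels else any_fm.channel_names
    rng = np.random.default_rng(seed)
    net = build_network(spec, len(channels), rng)
    optimizer = _nn.RMSprop(
        net.params(),
        lr=opts.learning_rate,
        rho=opts.rho,
        l1={"first_layer": opts.l1_first_layer, "other": opts.l1_other},
    )

    val_windows: list[Window] = []
    if opts.early_stopping and len(windows) >= 8:
        n_val = max(1, int(round(len(windows) * opts.validation_fraction)))
        order = rng.permutation(len(windows))
        val_windows = [windows[i] for i in order[:n_val]]
        windows = [windows[i] for i in order[n_val:]]
    data = [_window_xy(w, store, labels, channels) for w in windows]
    val_data = [_window_xy(w, store, labels, channels) for w in val_windows]

    log: list[dict] = []
    best_state, best_metric, since_best = None, -np.inf, 0
    for epoch in range(opts.epochs):
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for b0 in range(0, len(order), opts.batch_size):
            batch = order[b0 : b0 + opts.batch_size]
            optimizer.zero_grad()
            for i in batch:
                x, y = data[i]
                logits = net.forward(x, train=True, rng=rng)
                loss, dlogits = _nn.cross_entropy(logits, y)
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}, window {i}"
                    )
                net.backward(dlogits / len(batch))
                epoch_loss += loss / len(data)
            optimizer.step()
        entry = {"epoch": epoch, "loss": epoch_loss}
        if val_data:
            val_f1 = _f1_at_half(net, *zip(*val_data))
            entry["val_f1"] = val_f1
            if val_f1 > best_metric:
                best_metric, best_state, since_best = val_f1, net.state(), 0
            else:
                since_best += 1
        log.append(entry)
        if val_data and since_best >= opts.patience:
            break
    if best_state is not None:
        net.load_state(best_state)
    return TrainedModel(spec, net, channels, log, seed)


def predict(
    model: TrainedModel,
    fm: FeatureMatrix,
    start: int,
    end: int,
    chunk: int = 100_000,
) -> np.ndarray:
    """Probability vector over [start, end); long CNN ranges are chunked.

    Chunks overlap by the receptive-field half-width so the stitched
    output is bit-identical to a single pass. Recurrent models carry
    unbounded context and are evaluated in a single pass.
    """
    missing = set(model.channel_names) - set(fm.channel_names)
    if missing:
        raise ValueError(f"feature matrix lacks model channels: {sorted(missing)}")
    if not 0 <= start <= end <= fm.length:
        raise IndexError("prediction range outside chromosome")
    if start == end:
        return np.empty(0)
    if model.spec.kind != "cnn" or end - start <= chunk:
        x = fm.dense(start, end, model.channel_names)
        return model.predict_window(x)
    halo = (receptive_field(model.spec) - 1) // 2
    out = np.empty(end - start)
    for a in range(start, end, chunk):
        b = min(a + chunk, end)
        pa, pb = max(start, a - halo), min(end, b + halo)
        x = fm.dense(pa, pb, model.channel_names)
        probs = model.predict_window(x)
        out[a - start : b - start] = probs[a - pa : a - pa + (b - a)]
    return out


# -- checkpointing ------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    payload = {
        f"param_{i}": p.value for i, p in enumerate(model.net.params())
    }
    meta = {
        "spec": model.spec.to_dict(),
        "channel_names": model.channel_names,
        "seed": model.seed,
        "training_log": model.training_log,
    }
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), np.uint8)
    np.savez(path, **payload)


def load_model(path) -> TrainedModel:
    npz = np.load(path)
    meta = json.loads(bytes(npz["meta"]).decode())
    spec = ModelSpec.from_dict(meta["spec"])
    net = build_network(spec, len(meta["channel_names"]), np.random.default_rng(0))
    params = net.params()
    for i, p in enumerate(params):
        p.value[...] = npz[f"param_{i}"]
    return TrainedModel(
        spec, net, list(meta["channel_names"]), list(meta["training_log"]), int(meta["seed"])
    )
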