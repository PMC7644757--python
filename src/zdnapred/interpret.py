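"""Model interpretation: L1-pruned feature importance and motif extraction.

Recurrent architectures are poor interpretation targets, so both analyses
use a CNN-only model. Feature importance trains the CNN with L1 penalties
(applied proximally, so unnecessary first-layer weights become exactly
zero), keeps each feature's first-layer weight of maximal absolute value,
and normalizes positives by the maximum positive and negatives by the
largest negative magnitude.

Motif extraction freezes the trained CNN and optimizes its *input*: first
an unconstrained patch (values clipped to [-1, 1] after every RMSprop
step) maximizing the central nucleotide's Z probability; then a separate
constrained solve for the four sequence channels only, with each column
on the probability simplex (entries >= 0, summing to 1), via sequential
least squares programming. The patch width equals the receptive field —
for the two-layer kernel-5 CNN, 9 nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _nn
from .dataset import WindowSet
from .features import FeatureMatrix, SEQ_CHANNELS
from .model_zoo import (
    ModelSpec,
    TrainOptions,
    TrainedModel,
    receptive_field,
    train,
)
from .sparse_store import SparseTrack

__all__ = [
    "ImportanceReport",
    "MotifMatrix",
    "MaximizedInput",
    "l1_importance",
    "maximize_input",
    "extract_motif",
    "project_columns_to_simplex",
]


@dataclass(frozen=True)
class ImportanceEntry:
    feature: str
    raw_weight: float
    normalized: float


@dataclass
class ImportanceReport:
    """Signed per-feature weights, normalized within each sign group."""

    entries: list[ImportanceEntry]

    def positive_ranking(self) -> list[ImportanceEntry]:
        pos = [e for e in self.entries if e.raw_weight > 0]
        return sorted(pos, key=lambda e: -e.normalized)

    def negative_ranking(self) -> list[ImportanceEntry]:
        neg = [e for e in self.entries if e.raw_weight < 0]
        return sorted(neg, key=lambda e: e.normalized)

    def score(self, feature: str) -> float:
        for e in self.entries:
            if e.feature == feature:
                return e.normalized
        raise KeyError(feature)

    def features(self) -> list[str]:
        return [e.feature for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": e.feature,
                    "sign": "positive" if e.raw_weight > 0 else "negative",
                    "raw_weight": e.raw_weight,
                    "normalized": e.normalized,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _first_conv_weights(model: TrainedModel) -> np.ndarray:
    if model.spec.kind != "cnn":
        raise ValueError("importance analysis requires a CNN-only model")
    for layer in model.net.layers:
        if isinstance(layer, _nn.Conv1d):
            return layer.W.value
    raise ValueError("model has no convolutional layer")


def importance_from_weights(
    weights: np.ndarray, channel_names: list[str]
) -> ImportanceReport:
    """Rank channels by their extreme first-layer weight.

    Per channel the signed weight of maximal absolute value is kept;
    channels whose first-layer weights are all exactly zero are dropped.
    Positive weights are divided by the maximum positive weight, negative
    weights by the largest negative magnitude, so the top feature in each
    sign group scores +/-1.
    """
    raw = {}
    for i, name in enumerate(channel_names):
        w = weights[:, i, :]
        if not np.any(w != 0.0):
            continue
        raw[name] = float(w.flat[np.argmax(np.abs(w))])
    pos_max = max((v for v in raw.values() if v > 0), default=None)
    neg_max = max((-v for v in raw.values() if v < 0), default=None)
    entries = []
    for name, v in raw.items():
        norm = v / pos_max if v > 0 else (v / neg_max if v < 0 else 0.0)
        entries.append(ImportanceEntry(name, v, float(norm)))
    entries.sort(key=lambda e: -abs(e.normalized))
    return ImportanceReport(entries)


def l1_importance(
    spec: ModelSpec,
    ws: WindowSet,
    store: dict[str, FeatureMatrix],
    labels: dict[str, SparseTrack | np.ndarray],
    l1_weights: tuple[float, float] = (1e-2, 1e-3),
    opts: TrainOptions | None = None,
    seed: int = 0,
) -> tuple[ImportanceReport, TrainedModel]:
    """Train the CNN under L1 regularization and rank the input features.

    ``l1_weights`` is the (first-layer, remaining-parameters) penalty
    pair; the default puts the stronger penalty on the first layer, whose
    weights gate the input features — nullifying unnecessary features is
    the point of the pruning. Either ordering is runnable.
    """
    if spec.kind != "cnn":
        raise ValueError("importance analysis requires a CNN-only spec")
    opts = replace(
        opts or TrainOptions(), l1_first_layer=l1_weights[0], l1_other=l1_weights[1]
    )
    model = train(spec, ws, store, labels, opts=opts, seed=seed)
    report = importance_from_weights(_first_conv_weights(model), model.channel_names)
    return report, model


# -- input maximization -------------------------------------------------


@dataclass
class MaximizedInput:
    patch: np.ndarray  # (C, W)
    objective: float
    converged: bool


def _central_objective(net: _nn.Sequential, patch: np.ndarray):
    """Central-position Z objective: probability, logit margin, margin grad.

    The quantity maximized is the class-1 probability of the central
    nucleotide; the ascent itself follows the logit margin z1 - z0, a
    strictly monotone transform with the same maximizer whose gradient
    does not vanish when the softmax saturates near probability 1.
    """
    W = patch.shape[1]
    center = W // 2
    logits = net.forward(patch, train=False)
    probs = _nn.softmax(logits[:, center : center + 1])[:, 0]
    margin = float(logits[1, center] - logits[0, center])
    dlogits = np.zeros_like(logits)
    dlogits[0, center] = -1.0
    dlogits[1, center] = 1.0
    dpatch = net.backward(dlogits)
    return float(probs[1]), margin, dpatch


def maximize_input(
    model: TrainedModel,
    learning_rate: float = 1e-2,
    value_range: tuple[float, float] = (-1.0, 1.0),
    iterations: int = 500,
    tol: float = 1e-9,
    rng=None,
) -> MaximizedInput:
    """RMSprop ascent on a frozen CNN's central Z probability.

    The trainable patch spans the receptive field; after every step the
    values are clipped to ``value_range`` (widened to [-1, 1] so both
    positively and negatively influencing features are visible).
    """
    W = receptive_field(model.spec)
    C = len(model.channel_names)
    rng = rng or np.random.default_rng(0)
    x = rng.uniform(-0.01, 0.01, (C, W))
    cache = np.zeros_like(x)
    best_x, best_margin = x.copy(), -np.inf
    last_improve = 0
    it = -1
    for it in range(iterations):
        _, margin, grad = _central_objective(model.net, x)
        if margin > best_margin + tol:
            best_margin, best_x, last_improve = margin, x.copy(), it
        cache = 0.9 * cache + 0.1 * grad**2
        x = x + learning_rate * grad / (np.sqrt(cache) + 1e-8)
        np.clip(x, value_range[0], value_range[1], out=x)
        if it - last_improve > 50:
            break
    _, final_margin, _ = _central_objective(model.net, x)
    if final_margin > best_margin:
        best_margin, best_x = final_margin, x.copy()
    converged = it < iterations - 1
    best_prob, _, _ = _central_objective(model.net, best_x)
    return MaximizedInput(best_x, best_prob, converged)


# -- constrained motif extraction ---------------------------------------


@dataclass
class MotifMatrix:
    """4 x W sequence weight matrix; each column is a simplex point."""

    matrix: np.ndarray
    alphabet: str = "ACGT"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, np.float64)
        if self.matrix.shape[0] != 4:
            raise ValueError("motif matrix must have 4 rows (A, C, G, T)")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        half = (self.width - 1) // 2
        return np.arange(-half, half + 1)

    def consensus(self) -> str:
        return "".join(self.alphabet[i] for i in np.argmax(self.matrix, axis=0))

    def to_meme(self, path, name: str = "motif_1") -> None:
        """Minimal MEME motif format for downstream comparison tools."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write("strands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for col in self.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")


def project_columns_to_simplex(mat: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    out = np.empty_like(mat, dtype=np.float64)
    for j in range(mat.shape[1]):
        v = np.asarray(mat[:, j], np.float64)
        u = np.sort(v)[::-1]
        css = np.cumsum(u) - 1.0
        rho = np.flatnonzero(u - css / np.arange(1, len(v) + 1) > 0)[-1]
        theta = css[rho] / (rho + 1.0)
        out[:, j] = np.maximum(v - theta, 0.0)
    return out


def extract_motif(
    model: TrainedModel,
    fixed_input: np.ndarray | None = None,
    seq_channels: tuple[str, ...] = SEQ_CHANNELS,
    max_iterations: int = 200,
) -> MotifMatrix:
    """Simplex-constrained maximization over the sequence channels.

    The four one-hot channels are mutually dependent (each column of a
    real sequence sums to 1), so they are optimized jointly under
    per-column simplex constraints with SLSQP while every non-sequence
    channel stays fixed — by default at the unconstrained box-optimal
    patch. The result is a 4 x W weight matrix interpretable as a Z-DNA
    propensity motif.
    """
    idx = []
    for name in seq_channels:
        if name not in model.channel_names:
            raise ValueError(f"sequence channel {name!r} not in model channels")
        idx.append(model.channel_names.index(name))
    idx = np.asarray(idx)
    if fixed_input is None:
        fixed_input = maximize_input(model).patch
    W = fixed_input.shape[1]
    patch = np.asarray(fixed_input, np.float64).copy()

    def objective(flat: np.ndarray):
        patch[idx] = flat.reshape(4, W)
        _, margin, grad = _central_objective(model.net, patch)
        return -margin, -grad[idx].ravel()

    x0 = project_columns_to_simplex(patch[idx]).ravel()
    col = np.repeat(np.arange(W)[None, :], 4, axis=0).ravel()
    cons_jac = np.zeros((W, 4 * W))
    for j in range(W):
        cons_jac[j, col == j] = 1.0
    constraints = {
        "type": "eq",
        "fun": lambda flat: flat.reshape(4, W).sum(axis=0) - 1.0,
        "jac": lambda flat: cons_jac,
    }
    res = minimize(
        objective,
        x0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * (4 * W),
        constraints=[constraints],
        options={"maxiter": max_iterations, "ftol": 1e-10},
    )
    mat = np.clip(res.x.reshape(4, W), 0.0, None)
    mat /= mat.sum(axis=0, keepdims=True)
    return MotifMatrix(mat)
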