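"""Whole-genome annotation: cross-fold ensembling, F1-optimal threshold,
and region assembly.

The window set is split into k (default 5) stratified folds; one model is
trained per held-out fold and each trained model predicts over the full
genome. The per-nucleotide probability is the arithmetic mean of the k
model outputs. The cutoff threshold maximizes nucleotide F1 over the
united window set; nucleotides above the threshold (strictly) form runs
that are joined across gaps shorter than 11 bp and kept only when at
least 11 bp long — one turn of the double helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import WindowSet
from .features import FeatureMatrix
from .intervals import RegionSet, _merge_sorted
from .model_zoo import ModelSpec, TrainOptions, train
from .sparse_store import SparseTrack

__all__ = [
    "ProbabilityTrack",
    "cross_fold_annotate",
    "select_threshold",
    "assemble_regions",
    "combine_annotations",
    "write_bedgraph",
]

JOIN_GAP = 11
MIN_LENGTH = 11
COMBINE_PROXIMITY = 10


@dataclass
class ProbabilityTrack:
    """Per-chromosome Z-DNA probability vectors with model provenance."""

    tracks: dict[str, np.ndarray]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        for chrom, v in self.tracks.items():
            v = np.asarray(v, np.float64)
            if v.min() < 0.0 or v.max() > 1.0:
                raise ValueError(f"probabilities outside [0, 1] on {chrom}")
            self.tracks[chrom] = v

    def chromosomes(self) -> list[str]:
        return sorted(self.tracks)


def ensemble_average(
    predictions: list[dict[str, np.ndarray]], provenance: list[str]
) -> ProbabilityTrack:
    """Arithmetic mean of per-model probability tracks (fold-order invariant)."""
    if not predictions:
        raise ValueError("no predictions to average")
    chroms = set(predictions[0])
    if any(set(p) != chroms for p in predictions):
        raise ValueError("models predicted different chromosome sets")
    mean = {
        c: np.mean([p[c] for p in predictions], axis=0) for c in sorted(chroms)
    }
    return ProbabilityTrack(mean, list(provenance))


def cross_fold_annotate(
    ws: WindowSet,
    spec: ModelSpec,
    store: dict[str, FeatureMatrix],
    labels: dict[str, SparseTrack | np.ndarray],
    seed: int = 0,
    opts: TrainOptions | None = None,
    train_fn=None,
) -> ProbabilityTrack:
    """Train one model per fold, predict genome-wide, average.

    ``train_fn(spec, fold_ws, store, labels, seed)`` must return an object
    with ``predict_track(store)``; by default the standard trainer is
    used, fitting each model only on its 4 training folds.
    """
    if not ws.folds:
        raise ValueError("window set has no fold assignment")

    def default_train(spec, fold_ws, store, labels, fold_seed):
        return train(spec, fold_ws, store, labels, opts=opts, seed=fold_seed)

    train_fn = train_fn or default_train
    predictions, provenance = [], []
    for fold in ws.fold_ids():
        fold_ws = ws.fold_view(fold)
        model = train_fn(spec, fold_ws, store, labels, seed + fold)
        predictions.append(model.predict_track(store))
        provenance.append(f"fold{fold}")
    return ensemble_average(predictions, provenance)


def _window_values(
    track: ProbabilityTrack,
    labels: dict[str, SparseTrack | np.ndarray],
    ws: WindowSet | None,
):
    probs, labs = [], []
    if ws is None:
        for chrom in track.chromosomes():
            lab = labels[chrom]
            lab = lab.materialize() if isinstance(lab, SparseTrack) else np.asarray(lab)
            probs.append(track.tracks[chrom])
            labs.append(lab)
    else:
        for w in ws.windows:
            lab = labels[w.chromosome]
            if isinstance(lab, SparseTrack):
                lab = lab.slice(w.start, w.end)
            else:
                lab = np.asarray(lab)[w.start : w.end]
            probs.append(track.tracks[w.chromosome][w.start : w.end])
            labs.append(lab)
    return np.concatenate(probs), (np.concatenate(labs) > 0).astype(np.int64)


def select_threshold(
    track: ProbabilityTrack,
    labels: dict[str, SparseTrack | np.ndarray],
    ws: WindowSet | None = None,
) -> float:
    """F1-maximizing cutoff over the observed probability values.

    Candidates are the distinct observed probabilities; each candidate t
    is scored by the F1 of calling every nucleotide with probability >= t
    (every distinct call set is realized by some candidate). Ties in F1
    resolve to the smallest threshold. When a window set is given, only
    its windows (the united folds) contribute nucleotides.
    """
    probs, labs = _window_values(track, labels, ws)
    n_pos = int(labs.sum())
    if n_pos == 0:
        raise ValueError("no positive nucleotides; threshold undefined")
    order = np.argsort(-probs, kind="stable")
    sorted_probs = probs[order]
    tp_cum = np.cumsum(labs[order])
    # descending unique block starts; predictions "prob >= t" for t equal
    # to a block's value include everything up to the block's end
    uniq, first_idx = np.unique(-sorted_probs, return_index=True)
    uniq = -uniq  # descending unique values
    n_called = np.append(first_idx[1:], len(sorted_probs))
    tp = tp_cum[n_called - 1]
    precision = tp / n_called
    recall = tp / n_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    best_f1 = f1.max()
    candidates = uniq[f1 >= best_f1 - 1e-12]
    return float(candidates.min())


def assemble_regions(
    track: ProbabilityTrack,
    threshold: float,
    join_gap: int = JOIN_GAP,
    min_length: int = MIN_LENGTH,
) -> RegionSet:
    """Threshold -> join -> length-filter, per chromosome.

    Maximal runs of probability strictly above the threshold are merged
    when separated by a gap smaller than ``join_gap`` (a gap of exactly
    ``join_gap`` stays split), then intervals shorter than ``min_length``
    are dropped (exactly ``min_length`` is kept). Interval scores are the
    mean probability over the final interval.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    intervals: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for chrom in track.chromosomes():
        p = track.tracks[chrom]
        mask = p > threshold
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        runs = edges.reshape(-1, 2)
        merged = _merge_sorted(runs, max(1, join_gap)) if len(runs) else runs
        if len(merged):
            keep = (merged[:, 1] - merged[:, 0]) >= min_length
            merged = merged[keep]
        intervals[chrom] = np.asarray(merged, np.int64).reshape(-1, 2)
        scores[chrom] = np.array([p[s:e].mean() for s, e in intervals[chrom]])
    return RegionSet(intervals, scores)


def combine_annotations(
    a: RegionSet, b: RegionSet, proximity: int = COMBINE_PROXIMITY
) -> RegionSet:
    """Union of two annotations, merging regions closer than ``proximity``."""
    return a.union(b).merge_close(max(1, proximity))


def write_bedgraph(path, track: ProbabilityTrack, precision: int = 4) -> None:
    """Probability track as a run-compressed bedGraph (browser-loadable)."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            p = np.round(track.tracks[chrom], precision)
            change = np.flatnonzero(p[1:] != p[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(p)]))
            for s, e in zip(starts, ends):
                if p[s] != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{p[s]:.{precision}g}\n")


def read_bedgraph_track(path, chrom_lengths: dict[str, int]) -> ProbabilityTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={0: str},
    )
    tracks = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for row in df.itertuples(index=False):
        if row.chrom in tracks:
            tracks[row.chrom][int(row.start) : int(row.end)] = row.value
    return ProbabilityTrack(tracks)
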