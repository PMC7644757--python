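"""Fixed-length labelled windows with stratified splits and folds.

Chromosomes are evenly tiled into windows (default 5000 nt, trailing
partial windows dropped) so window boundaries never depend on label
positions. The training pool keeps every window containing at least one
labelled nucleotide plus a fixed multiple (default 3x) of background
windows sampled genome-wide without replacement. Train/test splitting and
cross-validation folds are stratified by (chromosome, label presence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sparse_store import SparseTrack

__all__ = ["Window", "WindowSet", "tile_and_select", "stratified_split", "make_folds"]


@dataclass(frozen=True)
class Window:
    chromosome: str
    start: int
    end: int
    contains_z: bool


@dataclass(frozen=True)
class WindowSet:
    windows: tuple[Window, ...]
    window_length: int
    seed: int
    split: dict[int, str] = field(default_factory=dict)  # index -> train|test
    folds: dict[int, int] = field(default_factory=dict)  # index -> 1..k

    def __len__(self) -> int:
        return len(self.windows)

    def indices(self, split: str | None = None) -> list[int]:
        if split is None:
            return list(range(len(self.windows)))
        return [i for i in range(len(self.windows)) if self.split.get(i) == split]

    def subset(self, indices) -> list[Window]:
        return [self.windows[i] for i in indices]

    def train_windows(self) -> list[Window]:
        idx = self.indices("train")
        return self.subset(idx) if self.split else list(self.windows)

    def test_windows(self) -> list[Window]:
        return self.subset(self.indices("test"))

    def fold_ids(self) -> list[int]:
        return sorted(set(self.folds.values()))

    def fold_view(self, fold: int) -> "WindowSet":
        """Split view for one CV round: held-out fold = test, rest = train."""
        if not self.folds:
            raise ValueError("fold assignment missing")
        split = {
            i: ("test" if self.folds[i] == fold else "train")
            for i in range(len(self.windows))
        }
        return replace(self, split=split)

    def to_bed6(self, path) -> None:
        rows = []
        for i, w in enumerate(self.windows):
            name = self.split.get(i, "all")
            if i in self.folds:
                name += f"/fold{self.folds[i]}"
            rows.append(
                (w.chromosome, w.start, w.end, name, int(w.contains_z), ".")
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _label_sum(labels, chrom: str, start: int, end: int) -> float:
    track = labels[chrom]
    if isinstance(track, SparseTrack):
        return float(track.slice(start, end).sum())
    return float(np.asarray(track)[start:end].sum())


def tile_and_select(
    labels: dict[str, SparseTrack | np.ndarray],
    window_length: int = 5000,
    background_ratio: int = 3,
    seed: int = 0,
) -> WindowSet:
    """Tile chromosomes and select labelled plus sampled background windows.

    Every complete window containing >= 1 labelled nucleotide is kept;
    ``background_ratio`` times that count of zero-label windows is sampled
    uniformly genome-wide without replacement under the fixed seed.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if background_ratio < 0:
        raise ValueError("background_ratio must be >= 0")
    z_windows: list[Window] = []
    candidates: list[Window] = []
    for chrom in sorted(labels):
        track = labels[chrom]
        length = track.length if isinstance(track, SparseTrack) else len(track)
        for start in range(0, length - window_length + 1, window_length):
            end = start + window_length
            if _label_sum(labels, chrom, start, end) > 0:
                z_windows.append(Window(chrom, start, end, True))
            else:
                candidates.append(Window(chrom, start, end, False))
    rng = np.random.default_rng(seed)
    n_bg = background_ratio * len(z_windows)
    if n_bg > len(candidates):
        warnings.warn(
            f"only {len(candidates)} background windows available "
            f"({n_bg} requested); taking all"
        )
        n_bg = len(candidates)
    chosen = rng.choice(len(candidates), size=n_bg, replace=False) if n_bg else []
    selected = z_windows + [candidates[i] for i in sorted(chosen)]
    selected.sort(key=lambda w: (w.chromosome, w.start))
    return WindowSet(tuple(selected), window_length, seed)


def _strata(ws: WindowSet) -> dict[tuple[str, bool], list[int]]:
    groups: dict[tuple[str, bool], list[int]] = {}
    for i, w in enumerate(ws.windows):
        groups.setdefault((w.chromosome, w.contains_z), []).append(i)
    return {key: groups[key] for key in sorted(groups)}


def stratified_split(
    ws: WindowSet, train_fraction: float = 0.8, seed: int = 0
) -> WindowSet:
    """Train/test split stratified by (chromosome, label presence).

    Per stratum the test size is ``round(n * (1 - train_fraction))``;
    strata of fewer than 2 windows go wholly to train.
    """
    if not len(ws):
        raise ValueError("empty window set")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    split: dict[int, str] = {}
    for key, members in _strata(ws).items():
        if len(members) < 2:
            warnings.warn(f"stratum {key} has <2 windows; assigning to train")
            for i in members:
                split[i] = "train"
            continue
        order = rng.permutation(len(members))
        n_test = int(round(len(members) * (1.0 - train_fraction)))
        test_set = {members[order[j]] for j in range(n_test)}
        for i in members:
            split[i] = "test" if i in test_set else "train"
    return replace(ws, split=split)


def make_folds(ws: WindowSet, k: int = 5, seed: int = 0) -> WindowSet:
    """K folds of near-equal size, stratified by (chromosome, label presence).

    Within every stratum members spread over folds differing by at most
    one; globally fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    counts = {f: 0 for f in range(1, k + 1)}
    folds: dict[int, int] = {}
    for _, members in _strata(ws).items():
        order = rng.permutation(len(members))
        # cycle through folds ordered by current global load
        fold_order = sorted(counts, key=lambda f: (counts[f], f))
        for j, oj in enumerate(order):
            f = fold_order[j % k]
            folds[members[oj]] = f
            counts[f] += 1
    return replace(ws, folds=folds)
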