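"""Run-length encoded container for genome-length feature vectors.

A multi-channel feature matrix over a mammalian genome (3e9 positions x
~1000 channels of 4-byte floats) does not fit in RAM dense. The tracks
used here are long constant stretches — binary ChIP-seq peak indicators
and piecewise-constant energy channels — so run-length encoding compresses
them by orders of magnitude while keeping exact random-access slicing.

A :class:`SparseTrack` stores only the maximal constant runs whose value
differs from a default (0 for omics channels); everything not covered by a
run is the default. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SparseTrack", "from_dense", "save_archive", "load_archive", "ArchiveReader"]


@dataclass(frozen=True)
class SparseTrack:
    """Genome-length numeric vector stored as constant runs.

    Parameters
    ----------
    length
        Total number of positions.
    starts, ends, values
        Parallel arrays describing maximal runs ``[start, end)`` carrying
        ``value``. Runs are sorted, non-overlapping, inside ``[0, length)``
        and never carry ``default_value``.
    default_value
        Value of every position not covered by a run.
    """

    length: int
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    default_value: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "starts", np.asarray(self.starts, np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, np.int64))
        object.__setattr__(self, "values", np.asarray(self.values, np.float64))
        if self.length <= 0:
            raise ValueError("track length must be positive")
        s, e = self.starts, self.ends
        if not (len(s) == len(e) == len(self.values)):
            raise ValueError("runs arrays must be parallel")
        if len(s):
            if (e <= s).any():
                raise ValueError("empty or inverted run")
            if s[0] < 0 or e[-1] > self.length:
                raise ValueError("run outside [0, length)")
            if (s[1:] < e[:-1]).any():
                raise ValueError("runs overlap or are unsorted")
            if np.any(self.values == self.default_value):
                raise ValueError("run carrying the default value")

    @property
    def n_runs(self) -> int:
        return len(self.starts)

    @property
    def runs(self) -> list[tuple[int, int, float]]:
        return list(zip(self.starts.tolist(), self.ends.tolist(), self.values.tolist()))

    # -- dense interop -------------------------------------------------

    def materialize(self) -> np.ndarray:
        return self.slice(0, self.length)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Dense sub-vector for ``[start, end)``; agrees with dense indexing."""
        if not (0 <= start <= end <= self.length):
            raise IndexError(f"slice [{start}, {end}) outside [0, {self.length}]")
        out = np.full(end - start, self.default_value, np.float64)
        if end == start or not len(self.starts):
            return out
        lo = int(np.searchsorted(self.ends, start, side="right"))
        hi = int(np.searchsorted(self.starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(self.starts[i]), start) - start
            b = min(int(self.ends[i]), end) - start
            if b > a:
                out[a:b] = self.values[i]
        return out

    # -- algebra helpers used by the feature builder -------------------

    def coverage(self) -> int:
        """Number of positions carrying a non-default value."""
        return int((self.ends - self.starts).sum())

    def value_range(self) -> tuple[float, float]:
        """(min, max) over the full dense vector without materializing it."""
        vals = self.values
        if self.coverage() < self.length or not len(vals):
            vals = np.append(vals, self.default_value)
        return float(vals.min()), float(vals.max())


def from_dense(values: np.ndarray, default_value: float = 0.0) -> SparseTrack:
    """Run-length encode a dense vector; exact round-trip with materialize."""
    values = np.asarray(values, np.float64)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("expected a non-empty 1-D vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    vals = values[starts]
    keep = vals != default_value
    return SparseTrack(len(values), starts[keep], ends[keep], vals[keep], default_value)


def from_intervals(
    intervals: np.ndarray, length: int, value: float = 1.0
) -> SparseTrack:
    """Binary-style track from possibly overlapping ``(start, end)`` rows."""
    iv = np.asarray(intervals, np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return SparseTrack(length)
    if iv.min() < 0 or iv[:, 1].max() > length:
        raise ValueError("interval outside [0, length)")
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    starts, ends = [], []
    cs, ce = int(iv[0, 0]), int(iv[0, 1])
    for s, e in iv[1:]:
        if s <= ce:
            ce = max(ce, int(e))
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = int(s), int(e)
    starts.append(cs)
    ends.append(ce)
    return SparseTrack(
        length, np.array(starts), np.array(ends), np.full(len(starts), value)
    )


# -- single-file archive (one named entry per track, lazily loadable) ---


def save_archive(path, tracks: dict[str, SparseTrack]) -> None:
    """Write tracks to one ``.npz`` archive, one group of entries per name."""
    payload = {}
    for name, t in tracks.items():
        payload[f"{name}::starts"] = t.starts
        payload[f"{name}::ends"] = t.ends
        payload[f"{name}::values"] = t.values
        payload[f"{name}::meta"] = np.array([t.length, t.default_value], np.float64)
    np.savez_compressed(path, **payload)


class ArchiveReader:
    """Lazy, by-name access to an archive written by :func:`save_archive`."""

    def __init__(self, path):
        self._npz = np.load(path)
        self.names = sorted(
            k[: -len("::meta")] for k in self._npz.files if k.endswith("::meta")
        )

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def load(self, name: str) -> SparseTrack:
        if name not in self.names:
            raise KeyError(name)
        meta = self._npz[f"{name}::meta"]
        return SparseTrack(
            int(meta[0]),
            self._npz[f"{name}::starts"],
            self._npz[f"{name}::ends"],
            self._npz[f"{name}::values"],
            float(meta[1]),
        )

    def close(self) -> None:
        self._npz.close()


def load_archive(path) -> dict[str, SparseTrack]:
    reader = ArchiveReader(path)
    try:
        return {name: reader.load(name) for name in reader.names}
    finally:
        reader.close()
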