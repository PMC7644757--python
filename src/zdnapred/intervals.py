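"""Genomic interval sets (0-based half-open) with BED interchange.

The region calls produced by the annotation pipeline, and the label
intervals it trains from, are both plain sorted, merged interval sets per
chromosome. BED is the interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionSet"]


def _merge_sorted(iv: np.ndarray, min_gap: int = 1) -> np.ndarray:
    """Merge sorted intervals; two intervals merge when gap < min_gap.

    ``min_gap=1`` merges only overlapping/bookended-with-gap-0 intervals
    (gap 0 means touching). A gap of exactly ``min_gap`` is NOT merged.
    """
    if len(iv) == 0:
        return iv.reshape(0, 2)
    out = [[int(iv[0, 0]), int(iv[0, 1])]]
    for s, e in iv[1:]:
        if int(s) - out[-1][1] < min_gap:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, np.int64)


@dataclass
class RegionSet:
    """Sorted, merged 0-based half-open intervals per chromosome."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_list(cls, regions, merge: bool = True) -> "RegionSet":
        """Build from ``(chrom, start, end)`` tuples; overlaps merged silently."""
        by_chrom: dict[str, list] = {}
        for chrom, start, end in regions:
            if end < start:
                raise ValueError(f"inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        out = {}
        for chrom, iv in by_chrom.items():
            arr = np.asarray(sorted(iv), np.int64).reshape(-1, 2)
            out[chrom] = _merge_sorted(arr) if merge else arr
        return cls(out)

    @classmethod
    def read_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        return cls.from_list(df.itertuples(index=False, name=None))

    def write_bed(self, path, name_prefix: str = "region") -> None:
        rows = []
        i = 0
        for chrom in sorted(self.intervals):
            scores = self.scores.get(chrom)
            for j, (s, e) in enumerate(self.intervals[chrom]):
                score = float(scores[j]) if scores is not None else 0.0
                rows.append((chrom, int(s), int(e), f"{name_prefix}_{i}", round(score, 6)))
                i += 1
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    # -- queries -------------------------------------------------------

    def chromosomes(self) -> list[str]:
        return sorted(self.intervals)

    def count(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def total_length(self) -> int:
        return int(
            sum((v[:, 1] - v[:, 0]).sum() for v in self.intervals.values() if len(v))
        )

    def __iter__(self):
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def merge_close(self, proximity: int) -> "RegionSet":
        """Merge intervals closer than ``proximity`` bp (strict)."""
        return RegionSet(
            {c: _merge_sorted(v, max(1, proximity)) for c, v in self.intervals.items()}
        )

    def union(self, other: "RegionSet") -> "RegionSet":
        out = {}
        for chrom in set(self.intervals) | set(other.intervals):
            parts = [
                rs.intervals[chrom]
                for rs in (self, other)
                if chrom in rs.intervals and len(rs.intervals[chrom])
            ]
            if not parts:
                out[chrom] = np.empty((0, 2), np.int64)
                continue
            arr = np.concatenate(parts)
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            out[chrom] = _merge_sorted(arr)
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Remove covered stretches (e.g. a user-supplied exclusion BED)."""
        out = {}
        for chrom, iv in self.intervals.items():
            mask = other.intervals.get(chrom)
            if mask is None or not len(mask) or not len(iv):
                out[chrom] = iv.copy()
                continue
            kept = []
            for s, e in iv:
                cur = int(s)
                lo = np.searchsorted(mask[:, 1], cur, side="right")
                for ms, me in mask[lo:]:
                    if ms >= e:
                        break
                    if ms > cur:
                        kept.append((cur, int(ms)))
                    cur = max(cur, int(me))
                if cur < e:
                    kept.append((cur, int(e)))
            out[chrom] = np.asarray(kept, np.int64).reshape(-1, 2)
        return RegionSet(out)
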