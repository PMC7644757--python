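"""Per-chromosome multi-channel feature matrices.

Each chromosome of length L is viewed as a 1-D "image" with C channels:
4 one-hot sequence channels (A, C, G, T), three B-Z transition-energy
channels (per-nucleotide dinucleotide energy plus two constant junction
channels), and one binary channel per omics marker, where a marker's peaks
from different tissues are aggregated as presence in any tissue. Every
channel is linearly scaled to [0, 1] and stored run-length encoded so the
full matrix fits in RAM.

Coordinates are 0-based half-open; BED is the native label/peak format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .intervals import RegionSet
from .sparse_store import SparseTrack, from_dense, from_intervals

__all__ = [
    "EnergyTable",
    "FeatureMatrix",
    "SEQ_CHANNELS",
    "ENERGY_CHANNELS",
    "load_energy_table",
    "one_hot_encode",
    "energy_channels",
    "aggregate_marker",
    "scale_channel",
    "encode_labels",
    "build_feature_matrix",
    "build_store",
    "load_genome",
    "read_marker_bed",
    "read_bedgraph",
    "load_manifest",
]

SEQ_CHANNELS = ("seq:A", "seq:C", "seq:G", "seq:T")
ENERGY_CHANNELS = ("energy:dinucleotide", "energy:bz_junction", "energy:zz_junction")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DINUCLEOTIDES = tuple(a + b for a in _BASES for b in _BASES)


@dataclass(frozen=True)
class EnergyTable:
    """Dinucleotide B->Z transition energies plus junction costs (kcal/mol).

    Lower energy means the step flips to the left-handed Z conformation
    more easily; alternating purine-pyrimidine steps such as d(CG) are the
    most Z-prone. Junction energies are the costs of one B-Z and one Z-Z
    boundary and enter the model as constant channels.
    """

    dinucleotide_energy: dict[str, float]
    bz_junction_energy: float
    zz_junction_energy: float

    def __post_init__(self) -> None:
        missing = set(DINUCLEOTIDES) - set(self.dinucleotide_energy)
        if missing:
            raise ValueError(f"energy table missing dinucleotides: {sorted(missing)}")
        vals = list(self.dinucleotide_energy.values()) + [
            self.bz_junction_energy,
            self.zz_junction_energy,
        ]
        if not np.isfinite(vals).all():
            raise ValueError("energies must be finite")

    @property
    def max_energy(self) -> float:
        """Least Z-favourable value in the table (used for N bases)."""
        return max(self.dinucleotide_energy.values())


def load_energy_table(path=None) -> EnergyTable:
    """Read the TSV energy table (``# key = value`` headers for junctions)."""
    if path is None:
        path = resources.files("zdnapred.data") / "bz_energies.tsv"
    keys: dict[str, float] = {}
    rows: dict[str, float] = {}
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    try:
                        keys[k.strip()] = float(v)
                    except ValueError:
                        pass
                continue
            a, b = line.split("\t")
            if not header_seen:
                header_seen = True  # column header row
                continue
            rows[a.strip().upper()] = float(b)
    for k in ("bz_junction", "zz_junction"):
        if k not in keys:
            raise ValueError(f"energy table header key '{k}' missing")
    return EnergyTable(rows, keys["bz_junction"], keys["zz_junction"])


# -- sequence encodings ------------------------------------------------


def one_hot_encode(sequence: str) -> np.ndarray:
    """4 x L one-hot matrix (rows A, C, G, T); N gives an all-zero column."""
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), np.uint8)
    out = np.zeros((4, len(seq)), np.float64)
    ok = np.zeros(len(seq), bool)
    for base, row in _BASE_INDEX.items():
        hit = codes == ord(base)
        out[row, hit] = 1.0
        ok |= hit
    ok |= codes == ord("N")
    if not ok.all():
        bad = seq[int(np.flatnonzero(~ok)[0])]
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return out


def energy_channels(sequence: str, table: EnergyTable) -> dict[str, np.ndarray]:
    """Raw (unscaled) energy channels for one chromosome.

    Position i carries the energy of dinucleotide (i, i+1); the final
    position repeats the previous value. Any step containing N gets the
    table's maximum (least Z-favourable) energy. Junction channels are
    constant genome-wide.
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    lut = np.full((128, 128), table.max_energy, np.float64)
    for dn, e in table.dinucleotide_energy.items():
        lut[ord(dn[0]), ord(dn[1])] = e
    codes = np.frombuffer(seq.encode("ascii"), np.uint8)
    dinuc = np.full(L, table.max_energy, np.float64)
    if L > 1:
        dinuc[:-1] = lut[codes[:-1], codes[1:]]
        dinuc[-1] = dinuc[-2]
    return {
        "energy:dinucleotide": dinuc,
        "energy:bz_junction": np.full(L, table.bz_junction_energy),
        "energy:zz_junction": np.full(L, table.zz_junction_energy),
    }


# -- track-level operations --------------------------------------------


def aggregate_marker(tissue_tracks: list[SparseTrack]) -> SparseTrack:
    """Presence of the marker in any tissue: element-wise logical OR."""
    if not tissue_tracks:
        raise ValueError("no tissue tracks to aggregate")
    length = tissue_tracks[0].length
    if any(t.length != length for t in tissue_tracks):
        raise ValueError("tissue tracks differ in length")
    pieces = [
        np.stack([t.starts, t.ends], axis=1)
        for t in tissue_tracks
        if t.n_runs
    ]
    if not pieces:
        return SparseTrack(length)
    return from_intervals(np.concatenate(pieces), length)


def scale_channel(track: SparseTrack) -> SparseTrack:
    """Min-max scale to [0, 1]; a constant track maps to all zeros."""
    lo, hi = track.value_range()
    if hi == lo:
        return SparseTrack(track.length)
    new_vals = (track.values - lo) / (hi - lo)
    new_default = (track.default_value - lo) / (hi - lo)
    return SparseTrack(track.length, track.starts, track.ends, new_vals, new_default)


def encode_labels(regions: RegionSet, length: int, chromosome: str) -> np.ndarray:
    """Boolean nucleotide array: 1 inside Z-DNA regions, 0 otherwise."""
    out = np.zeros(length, np.float64)
    for s, e in regions.intervals.get(chromosome, np.empty((0, 2), np.int64)):
        if s < 0 or e > length:
            raise ValueError(f"label region [{s}, {e}) outside chromosome")
        out[s:e] = 1.0
    return out


def label_track(regions: RegionSet, length: int, chromosome: str) -> SparseTrack:
    iv = regions.intervals.get(chromosome, np.empty((0, 2), np.int64))
    return from_intervals(iv, length)


# -- assembled per-chromosome matrix -----------------------------------


@dataclass
class FeatureMatrix:
    """Ordered channel view of one chromosome (all channels length L).

    Channel order: one-hot sequence first, then energy channels, then
    marker channels — stable across chromosomes.
    """

    chromosome: str
    length: int
    channels: list[tuple[str, SparseTrack]]

    def __post_init__(self) -> None:
        for name, t in self.channels:
            if t.length != self.length:
                raise ValueError(f"channel {name} length {t.length} != {self.length}")

    @property
    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels]

    def track(self, name: str) -> SparseTrack:
        for n, t in self.channels:
            if n == name:
                return t
        raise KeyError(name)

    def dense(self, start: int, end: int, names: list[str] | None = None) -> np.ndarray:
        """(C, end-start) dense block, rows in channel (or requested) order."""
        if names is None:
            return np.stack([t.slice(start, end) for _, t in self.channels])
        by_name = dict(self.channels)
        try:
            return np.stack([by_name[n].slice(start, end) for n in names])
        except KeyError as exc:
            raise KeyError(f"channel {exc.args[0]!r} not in feature matrix") from exc


def build_feature_matrix(
    chromosome: str,
    sequence: str,
    markers: dict[str, SparseTrack] | None = None,
    energy_table: EnergyTable | None = None,
) -> FeatureMatrix:
    """Assemble OHE + energy + marker channels, all scaled to [0, 1].

    The dinucleotide energy channel is min-max scaled per chromosome; the
    constant junction channels are divided by the table's maximum energy
    (a per-chromosome min-max would collapse a constant channel to zero).
    Marker channels are expected binary and pass through scaling unchanged.
    """
    L = len(sequence)
    channels: list[tuple[str, SparseTrack]] = []
    ohe = one_hot_encode(sequence)
    for row, name in enumerate(SEQ_CHANNELS):
        channels.append((name, from_dense(ohe[row])))
    if energy_table is not None:
        raw = energy_channels(sequence, energy_table)
        channels.append(
            ("energy:dinucleotide", scale_channel(from_dense(raw["energy:dinucleotide"])))
        )
        denom = max(
            energy_table.max_energy,
            energy_table.bz_junction_energy,
            energy_table.zz_junction_energy,
        )
        for name in ("energy:bz_junction", "energy:zz_junction"):
            const = float(raw[name][0]) / denom
            channels.append((name, SparseTrack(L, default_value=const)))
    for name in sorted(markers or {}):
        track = markers[name]
        lo, hi = track.value_range()
        if lo < 0.0 or hi > 1.0:
            track = scale_channel(track)
        channels.append((f"marker:{name}", track))
    return FeatureMatrix(chromosome, L, channels)


def build_store(
    genome: dict[str, str],
    marker_tracks: dict[str, dict[str, SparseTrack]] | None = None,
    energy_table: EnergyTable | None = None,
) -> dict[str, FeatureMatrix]:
    """Per-chromosome feature matrices with identical channel sets."""
    store = {}
    for chrom, seq in genome.items():
        markers = {
            name: per_chrom[chrom]
            for name, per_chrom in (marker_tracks or {}).items()
            if chrom in per_chrom
        }
        missing = set(marker_tracks or {}) - set(markers)
        for name in sorted(missing):
            markers[name] = SparseTrack(len(seq))
        store[chrom] = build_feature_matrix(chrom, seq, markers, energy_table)
    names = None
    for chrom, fm in store.items():
        if names is None:
            names = fm.channel_names
        elif fm.channel_names != names:
            raise ValueError("channel sets differ across chromosomes")
    return store


# -- readers ------------------------------------------------------------


def load_genome(fasta_path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_marker_bed(path, chrom_lengths: dict[str, int]) -> dict[str, SparseTrack]:
    """Binary peak BED -> per-chromosome indicator tracks."""
    regions = RegionSet.read_bed(path)
    out = {}
    for chrom, length in chrom_lengths.items():
        iv = regions.intervals.get(chrom, np.empty((0, 2), np.int64))
        iv = np.clip(iv, 0, length)
        out[chrom] = from_intervals(iv, length)
    return out


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, SparseTrack]:
    """Real-valued 4-column bedGraph -> per-chromosome tracks."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={0: str},
    )
    out = {}
    for chrom, length in chrom_lengths.items():
        sub = df[df["chrom"] == chrom].sort_values("start")
        dense = np.zeros(length, np.float64)
        for _, row in sub.iterrows():
            dense[max(0, int(row.start)) : min(length, int(row.end))] = row.value
        out[chrom] = from_dense(dense)
    return out


def load_manifest(path) -> list[dict]:
    """Channel manifest: list of {name, path, marker_class} entries."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["tracks"] if isinstance(doc, dict) else doc
    for e in entries:
        for key in ("name", "path"):
            if key not in e:
                raise ValueError(f"manifest entry missing '{key}': {e}")
        e.setdefault("marker_class", "TF")
    return entries


def subtract_blacklist(regions: RegionSet, blacklist: RegionSet | None) -> RegionSet:
    """Drop label stretches falling in a user-supplied exclusion BED."""
    if blacklist is None:
        return regions
    out = regions.subtract(blacklist)
    removed = regions.total_length() - out.total_length()
    if removed:
        warnings.warn(f"excluded {removed} labelled nucleotides via blacklist")
    return out
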