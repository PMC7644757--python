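"""Synthetic genomes with planted Z-prone regions and omics tracks.

The generator emulates the statistical structure the predictor assumes:
a small multi-chromosome genome of i.i.d. uniform ACGT background;
labelled regions averaging ~400 nt that carry a planted Z-prone
purine-pyrimidine motif (alternating GC by default) tiled to the region
length; informative binary tracks equal to the label indicator with
whole-peak Bernoulli dropout (mimicking ChIP-seq peak dropout across
tissues); and uninformative noise tracks of matched interval density. A
truth manifest records which tracks are informative and the planted
motif, so parameter-recovery experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .intervals import RegionSet
from .sparse_store import SparseTrack, from_intervals

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "planted_motif_matrix"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic fixture.

    Defaults: three chromosomes (so stratified splitting and folding are
    exercised) of 100 kb each, 12 regions with mean length 400 nt
    (the labelled-region scale of experimental Z-DNA maps), an alternating
    GC planted motif, four informative and eight noise tracks, and 10%
    whole-peak dropout.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 100_000
    n_regions: int = 12
    region_length_mean: float = 400.0
    region_length_sd: float = 80.0
    region_min_length: int = 100
    region_min_separation: int = 2_000
    planted_motif: str = "GC"
    n_informative_tracks: int = 4
    n_noise_tracks: int = 8
    track_flip_probability: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.chromosome_length, self.n_regions) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.track_flip_probability < 0.5:
            raise ValueError("flip probability must be in [0, 0.5)")
        if not set(self.planted_motif.upper()) <= set("ACGT"):
            raise ValueError("planted motif must be ACGT only")


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    labels: RegionSet
    marker_tracks: dict[str, dict[str, SparseTrack]]
    informative: list[str]
    noise: list[str]
    config: SyntheticConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir) -> None:
        """Emit FASTA + BED files + truth manifest (plain text)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.labels.write_bed(out / "labels.bed", name_prefix="zdna")
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        entries = []
        for name in sorted(self.marker_tracks):
            path = tracks_dir / f"{name}.bed"
            rows = []
            for chrom in sorted(self.marker_tracks[name]):
                t = self.marker_tracks[name][chrom]
                for s, e in zip(t.starts, t.ends):
                    rows.append(f"{chrom}\t{s}\t{e}\n")
            with open(path, "w") as fh:
                fh.writelines(rows)
            entries.append(
                {"name": name, "path": f"tracks/{name}.bed", "marker_class": "TF"}
            )
        manifest = {
            "tracks": entries,
            "truth": {
                "informative": self.informative,
                "noise": self.noise,
                "planted_motif": self.config.planted_motif,
            },
            "config": asdict(self.config),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


def planted_motif_matrix(motif: str, width: int, phase: int = 0) -> np.ndarray:
    """One-hot 4 x width matrix of the motif tiled starting at ``phase``."""
    rows = {b: i for i, b in enumerate("ACGT")}
    motif = motif.upper()
    mat = np.zeros((4, width))
    for j in range(width):
        mat[rows[motif[(j + phase) % len(motif)]], j] = 1.0
    return mat


def _place_regions(cfg: SyntheticConfig, rng) -> RegionSet:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_regions // cfg.n_chromosomes)
    per_chrom[: cfg.n_regions % cfg.n_chromosomes] += 1
    regions = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        placed: list[tuple[int, int]] = []
        for _ in range(int(per_chrom[ci])):
            length = int(
                max(
                    cfg.region_min_length,
                    round(rng.normal(cfg.region_length_mean, cfg.region_length_sd)),
                )
            )
            if length >= cfg.chromosome_length:
                raise ValueError("region longer than chromosome")
            for _attempt in range(1000):
                start = int(rng.integers(0, cfg.chromosome_length - length))
                end = start + length
                if all(
                    end + cfg.region_min_separation <= s
                    or e + cfg.region_min_separation <= start
                    for s, e in placed
                ):
                    placed.append((start, end))
                    break
            else:
                raise ValueError(
                    "could not place requested regions; genome too small"
                )
        regions.extend((chrom, s, e) for s, e in sorted(placed))
    return RegionSet.from_list(regions)


def _random_intervals_like(
    lengths: list[int], chrom_length: int, rng
) -> np.ndarray:
    iv = []
    for ln in lengths:
        ln = min(ln, chrom_length - 1)
        start = int(rng.integers(0, chrom_length - ln))
        iv.append((start, start + ln))
    return np.asarray(iv, np.int64).reshape(-1, 2)


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Build one fixture; byte-identical outputs under a fixed seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = _place_regions(cfg, rng)
    genome = {}
    motif = cfg.planted_motif.upper()
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(list("ACGT"), size=cfg.chromosome_length)
        for s, e in labels.intervals.get(chrom, []):
            tile = (motif * ((e - s) // len(motif) + 1))[: e - s]
            seq[s:e] = list(tile)
        genome[chrom] = "".join(seq)

    marker_tracks: dict[str, dict[str, SparseTrack]] = {}
    informative, noise = [], []
    region_lengths = [e - s for _, s, e in labels]
    for i in range(cfg.n_informative_tracks):
        name = f"inf_{i:02d}"
        informative.append(name)
        per_chrom = {}
        for chrom, L in ((c, len(genome[c])) for c in sorted(genome)):
            iv = labels.intervals.get(chrom, np.empty((0, 2), np.int64))
            keep = rng.random(len(iv)) >= cfg.track_flip_probability
            per_chrom[chrom] = from_intervals(iv[keep], L)
        marker_tracks[name] = per_chrom
    for i in range(cfg.n_noise_tracks):
        name = f"noise_{i:02d}"
        noise.append(name)
        per_chrom = {}
        n_per_chrom = max(1, len(region_lengths) // cfg.n_chromosomes)
        for chrom in sorted(genome):
            lengths = [
                int(region_lengths[int(rng.integers(0, len(region_lengths)))])
                for _ in range(n_per_chrom)
            ]
            per_chrom[chrom] = from_intervals(
                _random_intervals_like(lengths, len(genome[chrom]), rng),
                len(genome[chrom]),
            )
        marker_tracks[name] = per_chrom
    return SyntheticDataset(genome, labels, marker_tracks, informative, noise, cfg)
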