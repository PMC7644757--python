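"""Annotation: ensembling, threshold selection, region assembly rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import f1_score

from zdnapred import annotate, dataset
from zdnapred.annotate import (
    ProbabilityTrack,
    assemble_regions,
    combine_annotations,
    cross_fold_annotate,
    ensemble_average,
    select_threshold,
)
from zdnapred.intervals import RegionSet
from zdnapred.sparse_store import from_dense


def dense_scan_assemble(p, threshold, join_gap=11, min_length=11):
    """Independent O(L) oracle: walk the dense vector position by position."""
    runs = []
    start = None
    for i, v in enumerate(p):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(p)])
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < join_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_length]


class TestEnsemble:
    def test_constant_stub_models_average(self):
        preds = [{"chr1": np.full(10, v)} for v in (0.1, 0.2, 0.3, 0.4, 0.5)]
        track = ensemble_average(preds, [f"m{i}" for i in range(5)])
        np.testing.assert_allclose(track.tracks["chr1"], 0.3)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        preds = [{"chr1": rng.random(50)} for _ in range(5)]
        a = ensemble_average(preds, list("abcde"))
        b = ensemble_average(preds[::-1], list("edcba"))
        np.testing.assert_allclose(a.tracks["chr1"], b.tracks["chr1"])

    def test_cross_fold_uses_five_models(self):
        dense = np.zeros(500)
        dense[55:75] = 1.0
        dense[255:275] = 1.0
        labels = {"chr1": from_dense(dense)}
        ws = dataset.tile_and_select(labels, 50, 3, seed=0)
        ws = dataset.make_folds(ws, 5, seed=0)

        class Stub:
            def __init__(self, value):
                self.value = value

            def predict_track(self, store):
                return {"chr1": np.full(500, self.value)}

        values = iter([0.1, 0.2, 0.3, 0.4, 0.5])

        def train_fn(spec, fold_ws, store, labels, seed):
            return Stub(next(values))

        track = cross_fold_annotate(ws, None, {"chr1": None}, labels, train_fn=train_fn)
        assert len(track.provenance) == 5
        np.testing.assert_allclose(track.tracks["chr1"], 0.3)

    def test_missing_folds_rejected(self):
        labels = {"chr1": from_dense(np.ones(100))}
        ws = dataset.tile_and_select(labels, 50, 0, seed=0)
        with pytest.raises(ValueError, match="fold"):
            cross_fold_annotate(ws, None, {}, labels)


class TestSelectThreshold:
    def test_worked_example(self):
        track = ProbabilityTrack({"chr1": np.array([0.2, 0.6, 0.7])})
        labels = {"chr1": np.array([0.0, 1.0, 1.0])}
        assert select_threshold(track, labels) == 0.6

    def test_exact_recovery_gives_perfect_f1(self):
        rng = np.random.default_rng(1)
        probs = rng.random(500)
        labels = {"chr1": (probs > 0.5).astype(float)}
        track = ProbabilityTrack({"chr1": probs})
        t = select_threshold(track, labels)
        assert f1_score(labels["chr1"], probs >= t) == 1.0

    def test_no_positives_rejected(self):
        track = ProbabilityTrack({"chr1": np.array([0.2, 0.6])})
        with pytest.raises(ValueError, match="positive"):
            select_threshold(track, {"chr1": np.zeros(2)})

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(2)
        probs = rng.random(300).round(2)
        labels = (rng.random(300) < 0.2).astype(float)
        track = ProbabilityTrack({"chr1": probs})
        selected = select_threshold(track, {"chr1": labels})
        best = max(
            np.unique(probs),
            key=lambda t: (f1_score(labels, probs >= t), -t),
        )
        assert f1_score(labels, probs >= selected) == pytest.approx(
            f1_score(labels, probs >= best)
        )
        assert selected == best


class TestAssembleRegions:
    def test_nearby_runs_joined(self):
        p = np.zeros(50)
        p[0:15] = 0.9
        p[20:35] = 0.9  # gap of 5 < 11
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.5)
        assert [(s, e) for _, s, e in rs] == [(0, 35)]

    def test_boundary_gap_exactly_eleven_not_merged(self):
        p = np.zeros(60)
        p[0:15] = 0.9
        p[26:45] = 0.9  # gap exactly 11
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.5)
        assert [(s, e) for _, s, e in rs] == [(0, 15), (26, 45)]

    def test_boundary_lengths(self):
        p = np.zeros(100)
        p[0:8] = 0.9  # shorter than 11 -> dropped
        p[40:51] = 0.9  # exactly 11 -> kept
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.5)
        assert [(s, e) for _, s, e in rs] == [(40, 51)]

    def test_threshold_strictly_greater(self):
        p = np.full(30, 0.5)
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.5)
        assert rs.count() == 0

    def test_scores_are_mean_probability(self):
        p = np.zeros(40)
        p[5:20] = np.linspace(0.6, 0.9, 15)
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.5)
        assert rs.scores["chr1"][0] == pytest.approx(p[5:20].mean())

    def test_idempotent_on_indicator_reencoding(self):
        rng = np.random.default_rng(3)
        p = rng.random(2000)
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), 0.7)
        indicator = np.zeros(2000)
        for _, s, e in rs:
            indicator[s:e] = 1.0
        rs2 = assemble_regions(ProbabilityTrack({"chr1": indicator}), 0.5)
        np.testing.assert_array_equal(rs.intervals["chr1"], rs2.intervals["chr1"])

    def test_lower_threshold_never_covers_less_before_length_filter(self):
        rng = np.random.default_rng(4)
        p = rng.random(3000)
        cov = []
        for t in (0.9, 0.6, 0.3):
            rs = assemble_regions(ProbabilityTrack({"chr1": p}), t, min_length=1)
            cov.append(rs.total_length())
        assert cov[0] <= cov[1] <= cov[2]

    @given(st.integers(0, 2**31 - 1), st.floats(0.3, 0.9))
    def test_matches_dense_scan_oracle(self, seed, threshold):
        rng = np.random.default_rng(seed)
        p = rng.random(1500).round(1)  # plateaus force boundary cases
        rs = assemble_regions(ProbabilityTrack({"chr1": p}), threshold)
        assert [(s, e) for _, s, e in rs] == dense_scan_assemble(p, threshold)


class TestCombine:
    def test_far_regions_concatenate(self):
        a = RegionSet.from_list([("chr1", 0, 20)])
        b = RegionSet.from_list([("chr1", 100, 120), ("chr2", 5, 25)])
        out = combine_annotations(a, b)
        assert list(out) == [("chr1", 0, 20), ("chr1", 100, 120), ("chr2", 5, 25)]

    def test_regions_five_bp_apart_merge(self):
        a = RegionSet.from_list([("chr1", 0, 20)])
        b = RegionSet.from_list([("chr1", 25, 40)])
        assert list(combine_annotations(a, b)) == [("chr1", 0, 40)]

    def test_gap_exactly_proximity_not_merged(self):
        a = RegionSet.from_list([("chr1", 0, 20)])
        b = RegionSet.from_list([("chr1", 30, 40)])  # gap exactly 10
        assert combine_annotations(a, b).count() == 2

    def test_empty_identity(self):
        a = RegionSet.from_list([("chr1", 0, 20)])
        out = combine_annotations(a, RegionSet())
        assert list(out) == list(a)


def test_bedgraph_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    p = np.round(rng.random(400), 4)
    track = ProbabilityTrack({"chr1": p, "chr2": np.zeros(100)})
    path = tmp_path / "probs.bedgraph"
    annotate.write_bedgraph(path, track)
    loaded = annotate.read_bedgraph_track(path, {"chr1": 400, "chr2": 100})
    np.testing.assert_allclose(loaded.tracks["chr1"], p, atol=1e-12)
    np.testing.assert_array_equal(loaded.tracks["chr2"], 0.0)
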