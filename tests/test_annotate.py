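"""Genetic map interpolation, motif offsets, overlap, telomeres, signal."""

import numpy as np
import pandas as pd
import pytest

from gamrec import annotate as ann
from gamrec.classify import RecombinationEvent


def simple_map(anchors=((0, 0.0), (1_000_000, 2.0))):
    pos = np.array([a for a, _ in anchors], dtype=float)
    cm = np.array([c for _, c in anchors], dtype=float)
    return ann.GeneticMap({"chrS": (pos, cm)})


class TestGeneticMap:
    def test_linear_interpolation_example(self):
        g = simple_map()
        assert g.interval_cm("chrS", 250_000, 750_000) == pytest.approx(1.0)
        assert g.interval_rate("chrS", 250_000, 750_000) == pytest.approx(2.0)

    def test_additivity_random_anchors(self, rng):
        pos = np.sort(rng.choice(10_000_000, size=20, replace=False)).astype(float)
        cm = np.cumsum(rng.random(20))
        g = ann.GeneticMap({"chrS": (pos, cm)})
        lo, hi = pos[0], pos[-1]
        for _ in range(30):
            a, b, c = np.sort(rng.uniform(lo, hi, size=3))
            if a == b or b == c:
                continue
            assert g.interval_cm("chrS", a, c) == pytest.approx(
                g.interval_cm("chrS", a, b) + g.interval_cm("chrS", b, c))

    def test_clamped_outside_with_warning(self):
        g = simple_map()
        with pytest.warns(ann.MapBoundsWarning):
            val = g.cm_at("chrS", 2_000_000)
        assert val == pytest.approx(2.0)

    def test_monotonicity_required(self):
        with pytest.raises(ValueError):
            ann.GeneticMap({"chrS": (np.array([0.0, 10.0]), np.array([1.0, 0.5]))})

    def test_round_trip_text_format(self, tmp_path):
        p = tmp_path / "map.txt"
        p.write_text("chrom pos cM\nchrS 0 0.0\nchrS 1000000 2.0\n")
        g = ann.read_genetic_map(p)
        assert g.interval_cm("chrS", 0, 500_000) == pytest.approx(1.0)


class TestDetectableInterval:
    def test_examples(self):
        assert ann.detectable_interval([10, 20, 30, 40]) == (20, 30)
        assert ann.detectable_interval([5, 9, 14, 100, 200]) == (9, 100)
        assert ann.detectable_interval([10, 20, 30]) is None


def motif_set(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    return ann.MotifSet(df)


def co_event(rid, a, b):
    return RecombinationEvent(read_id=rid, sample_id="s", event_class="CO",
                              n_switches=1, labels="1122",
                              transitions=((a, b),))


def nco_event(rid, converted):
    return RecombinationEvent(read_id=rid, sample_id="s", event_class="NCO",
                              n_switches=2, labels="121",
                              converted_positions=tuple(converted))


class TestMotifOffsets:
    def test_co_interval_downstream_plus_strand(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "+")])  # centre 1000
        dist = ann.motif_offsets_co([co_event("r", 1100, 1200)], motifs,
                                    max_interval=500)
        assert dist.downstream_fraction() == 1.0
        assert dist.weights.sum() == pytest.approx(1.0)

    def test_minus_strand_flips_sign(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "-")])
        dist = ann.motif_offsets_co([co_event("r", 1100, 1200)], motifs,
                                    max_interval=500)
        assert dist.downstream_fraction() == 0.0

    def test_mirrored_events_balance(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "+")])
        events = [co_event("a", 1100, 1200), co_event("b", 800, 900)]
        dist = ann.motif_offsets_co(events, motifs, max_interval=500)
        assert dist.downstream_fraction() == pytest.approx(0.5)
        assert dist.weighted_median() == pytest.approx(0.0, abs=1.0)

    def test_long_interval_skipped(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "+")])
        dist = ann.motif_offsets_co([co_event("r", 1000, 2000)], motifs,
                                    max_interval=500)
        assert dist.offsets.size == 0

    def test_nco_single_marker_offset(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "+")])
        dist = ann.motif_offsets_nco([nco_event("r", [962])], motifs)
        assert dist.offsets.tolist() == [-38.0]

    def test_nco_multi_marker_weights(self):
        motifs = motif_set([("chrS", 985, 1016, "m", 0, "+")])
        dist = ann.motif_offsets_nco([nco_event("r", [990, 1030])], motifs)
        assert np.allclose(dist.weights, [0.5, 0.5])

    def test_translation_invariance_of_summaries(self):
        motifs_a = motif_set([("chrS", 985, 1016, "m", 0, "+")])
        motifs_b = motif_set([("chrS", 10_985, 11_016, "m", 0, "+")])
        d_a = ann.motif_offsets_co([co_event("r", 1100, 1200)], motifs_a,
                                   max_interval=500)
        d_b = ann.motif_offsets_co([co_event("r", 11_100, 11_200)], motifs_b,
                                   max_interval=500)
        assert d_a.weighted_mean_abs() == pytest.approx(d_b.weighted_mean_abs())
        assert d_a.downstream_fraction() == d_b.downstream_fraction()


class TestOverlapFractions:
    MOTIFS = motif_set([("chrS", 985, 1016, "m1", 0, "+"),
                        ("chrS", 5000, 5031, "m2", 0, "-")])

    def test_motif_in_span_but_not_interval(self):
        spans = {"r": (900, 1200)}
        inner = {"r": (1100, 1200)}
        res = ann.overlap_fractions(spans, self.MOTIFS, inner)
        assert res["overlap_fraction"] == 1.0
        assert res["center_inside_fraction"] == 0.0

    def test_no_motifs(self):
        empty = motif_set([])
        res = ann.overlap_fractions({"r": (0, 100)}, empty)
        assert res["overlap_fraction"] == 0.0

    def test_exhaustive_toy_oracle(self, rng):
        """Fractions equal direct interval arithmetic on a toy genome."""
        spans = {f"r{i}": (int(a), int(a) + 400)
                 for i, a in enumerate(rng.integers(0, 6000, size=40))}
        res = ann.overlap_fractions(spans, self.MOTIFS)
        direct = np.mean([
            (a < 1016 and 985 < b) or (a < 5031 and 5000 < b)
            for a, b in spans.values()])
        assert res["overlap_fraction"] == pytest.approx(direct)

    def test_monotone_in_motif_set(self, rng):
        spans = {f"r{i}": (int(a), int(a) + 400)
                 for i, a in enumerate(rng.integers(0, 6000, size=40))}
        sub = motif_set([("chrS", 985, 1016, "m1", 0, "+")])
        assert (ann.overlap_fractions(spans, sub)["overlap_fraction"]
                <= ann.overlap_fractions(spans, self.MOTIFS)["overlap_fraction"])


class TestTelomereDistances:
    def test_uniform_map_flat_expectation(self):
        g = simple_map(((0, 0.0), (50_000_000, 50.0)))
        reads = [np.arange(s, s + 100_000, 10_000)
                 for s in range(0, 20_000_000, 100_000)]
        out = ann.telomere_distances([], 50_000_000, reads, g,
                                     max_distance=10_000_000)
        expected = out["expected"].to_numpy()
        assert expected.std() / expected.mean() < 0.1

    def test_concentrated_map(self):
        g = ann.GeneticMap({"chrS": (np.array([0.0, 1e6, 1.1e6, 5e7]),
                                     np.array([0.0, 0.0, 10.0, 10.0]))})
        reads = [np.arange(s, s + 200_000, 20_000)
                 for s in range(0, 3_000_000, 200_000)]
        out = ann.telomere_distances([], 50_000_000, reads, g,
                                     max_distance=5_000_000)
        exp = out["expected"].to_numpy()
        assert exp[1] == pytest.approx(exp.sum(), rel=0.05)  # mass in 1-2 Mb bin

    def test_observed_histogram_toy_oracle(self):
        g = simple_map(((0, 0.0), (50_000_000, 50.0)))
        events = [500_000, 1_500_000, 49_800_000]  # last: 200 kb from far end
        out = ann.telomere_distances(events, 50_000_000, [], g,
                                     max_distance=5_000_000)
        obs = out["observed"].to_numpy()
        assert obs[0] == 2 and obs[1] == 1


class TestMeanSignal:
    def test_constant_track(self):
        t = ann.SignalTrack(pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "end": [1000], "value": [3.5]}))
        assert t.mean_signal("chrS", 100, 900) == pytest.approx(3.5)

    def test_half_and_half(self):
        t = ann.SignalTrack(pd.DataFrame(
            {"chrom": ["chrS", "chrS"], "start": [0, 500], "end": [500, 1000],
             "value": [0.0, 2.0]}))
        assert t.mean_signal("chrS", 0, 1000) == pytest.approx(1.0)

    def test_random_tracks_match_base_oracle(self, rng):
        starts = np.arange(0, 2000, 100)
        vals = rng.random(starts.size)
        t = ann.SignalTrack(pd.DataFrame(
            {"chrom": "chrS", "start": starts, "end": starts + 100,
             "value": vals}))
        base = np.repeat(vals, 100)
        for _ in range(10):
            a, b = np.sort(rng.integers(0, 2000, size=2))
            if a == b:
                continue
            assert t.mean_signal("chrS", a, b) == pytest.approx(
                base[a:b].mean())

    def test_zero_filled_outside(self):
        t = ann.SignalTrack(pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "end": [100], "value": [4.0]}))
        assert t.mean_signal("chrS", 0, 200) == pytest.approx(2.0)

    def test_empty_interval_rejected(self):
        t = ann.SignalTrack(pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "end": [100], "value": [4.0]}))
        with pytest.raises(ValueError):
            t.mean_signal("chrS", 50, 50)
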