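"""Genome-context annotation of recombination events.

Relates classified events and reads to external annotations that all
share the marker-table coordinate system: a genetic map (linear
interpolation of cumulative cM over anchor positions), stranded hotspot
motifs (31-bp PRDM9 binding sites at double-strand-break hotspots), a
signal track (bedGraph step function, e.g. H3K4me3 ChIP-seq), and
chromosome lengths for telomere-distance analyses.

Conventions: 0-based half-open intervals; a read's *detectable
interval* runs from its second to its second-to-last marker (an event
outside it could not have been classified); a CO is localised to the
interval between the two markers flanking its switch, an NCO to the
markers surrounding its converted tract.  Motif-relative offsets are
signed in the motif's orientation (positive = downstream) and flip sign
on minus-strand motifs.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classify import RecombinationEvent
from .stats import OffsetDistribution

__all__ = [
    "GeneticMap",
    "MotifSet",
    "SignalTrack",
    "read_genetic_map",
    "read_bed6",
    "read_bedgraph",
    "detectable_interval",
    "motif_offsets_co",
    "motif_offsets_nco",
    "overlap_fractions",
    "telomere_distances",
    "mean_signal",
]


class MapBoundsWarning(UserWarning):
    pass


@dataclass
class GeneticMap:
    """Per-chromosome genetic map: anchor positions (bp) with cumulative cM."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.anchors.items():
            pos = np.asarray(pos, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: anchor positions must increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cumulative cM must be non-decreasing")
            self.anchors[chrom] = (pos, cm)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {}
        for chrom, g in df.groupby("chrom", sort=False):
            g = g.sort_values("pos")
            anchors[str(chrom)] = (g["pos"].to_numpy(float), g["cm"].to_numpy(float))
        return cls(anchors)

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at position(s), clamped outside the anchor range."""
        p, c = self.anchors[chrom]
        pos = np.asarray(pos, dtype=np.float64)
        if np.any(pos < p[0]) or np.any(pos > p[-1]):
            warnings.warn(
                f"{chrom}: positions outside the map range were clamped",
                MapBoundsWarning, stacklevel=2)
        return np.interp(pos, p, c)

    def interval_cm(self, chrom: str, a: float, b: float) -> float:
        """Genetic length of [a, b) in cM (additive over abutting intervals)."""
        if a >= b:
            raise ValueError("need a < b")
        lo, hi = self.cm_at(chrom, (a, b))
        return float(hi - lo)

    def interval_rate(self, chrom: str, a: float, b: float) -> float:
        """Mean recombination rate over [a, b) in cM/Mb."""
        return self.interval_cm(chrom, a, b) / ((b - a) / 1e6)


def read_genetic_map(path) -> GeneticMap:
    """Whitespace text 'chrom pos cM'; a non-numeric header is tolerated."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["chrom", "pos", "cm"])
    if not str(df.iloc[0]["pos"]).replace(".", "").isdigit():
        df = df.iloc[1:]
    df["pos"] = df["pos"].astype(float)
    df["cm"] = df["cm"].astype(float)
    return GeneticMap.from_frame(df)


@dataclass
class MotifSet:
    """Stranded motif intervals with centre positions, per chromosome."""

    table: pd.DataFrame  # chrom, start, end, name, score, strand, center

    def __post_init__(self) -> None:
        t = self.table
        if not set(t["strand"]).issubset({"+", "-"}):
            raise ValueError("strand must be + or -")
        if "center" not in t.columns:
            t = t.assign(center=(t["start"] + t["end"]) // 2)
        bad = (t["center"] < t["start"]) | (t["center"] >= t["end"])
        if bad.any():
            raise ValueError("motif centers must lie inside their intervals")
        self.table = t.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, g in self.table.groupby("chrom"):
            self._trees[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e), i) for i, (s, e)
                in enumerate(zip(g["start"], g["end"]), start=g.index[0]))

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        tree = self._trees.get(chrom)
        if tree is None:
            return self.table.iloc[0:0]
        idx = sorted(iv.data for iv in tree.overlap(start, end))
        return self.table.loc[idx]

    def nearest_oriented(self, chrom: str, start: int, end: int) -> pd.Series | None:
        """Motif overlapping the span; ties broken by |centre - span
        midpoint|, then leftmost."""
        hits = self.overlapping(chrom, start, end)
        if not len(hits):
            return None
        mid = (start + end) / 2.0
        key = (hits["center"] - mid).abs()
        best = hits.assign(_d=key).sort_values(["_d", "start"]).iloc[0]
        return best.drop("_d")


def read_bed6(path) -> MotifSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return MotifSet(df)


@dataclass
class SignalTrack:
    """Step function over genome intervals (bedGraph semantics, zero-filled)."""

    table: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        parts = {}
        for chrom, g in self.table.groupby("chrom"):
            g = g.sort_values("start")
            s = g["start"].to_numpy(np.int64)
            e = g["end"].to_numpy(np.int64)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping signal intervals")
            parts[str(chrom)] = (s, e, g["value"].to_numpy(np.float64))
        self._parts = parts

    def mean_signal(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean of the step function over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        part = self._parts.get(chrom)
        if part is None:
            return 0.0
        s, e, v = part
        lo = np.clip(s, start, end)
        hi = np.clip(e, start, end)
        covered = np.maximum(hi - lo, 0)
        return float(np.sum(covered * v) / (end - start))


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    return SignalTrack(df)


def mean_signal(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    return track.mean_signal(chrom, start, end)


# ---------------------------------------------------------------------------
# Read- and event-level annotations


def detectable_interval(positions: Sequence[int]) -> tuple[int, int] | None:
    """[2nd marker, 2nd-to-last marker) of a read; None below 4 markers.

    Events outside this interval cannot receive two flanking markers on
    both sides, so per-read comparisons of genetic length use it rather
    than the full read span.
    """
    x = np.asarray(positions)
    if x.size < 4:
        return None
    return int(x[1]), int(x[-2])


def _oriented_offset(pos, center: int, strand: str):
    off = np.asarray(pos, dtype=np.float64) - center
    return -off if strand == "-" else off


def motif_offsets_co(
    events: Iterable[RecombinationEvent],
    motifs: MotifSet,
    chrom_of: Mapping[str, str] | str = "chrS",
    max_interval: int = 500,
    search_flank: int = 20_000,
) -> OffsetDistribution:
    """Base-weighted CO-interval offsets relative to the nearest motif.

    Each base of a CO interval (the span between the switch-flanking
    markers) shorter than ``max_interval`` bp contributes weight
    1/interval_length at its oriented offset from the motif centre.
    The motif is the nearest oriented one within ``search_flank`` bp of
    the interval (read scale: the hotspot motif need not fall inside
    the localisation interval itself); events with none are skipped.
    """
    offs, wts, rids = [], [], []
    for ev in events:
        if ev.event_class != "CO" or not ev.transitions:
            continue
        a, b = ev.transitions[0]
        if b - a > max_interval or b <= a:
            continue
        chrom = chrom_of if isinstance(chrom_of, str) else chrom_of[ev.read_id]
        hit = motifs.nearest_oriented(chrom, a - search_flank, b + search_flank)
        if hit is None:
            continue
        bases = np.arange(a, b)
        off = _oriented_offset(bases, int(hit["center"]), hit["strand"])
        offs.append(off)
        wts.append(np.full(off.size, 1.0 / off.size))
        rids.append(np.full(off.size, ev.read_id, dtype=object))
    if not offs:
        return OffsetDistribution(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    return OffsetDistribution(np.concatenate(offs), np.concatenate(wts),
                              np.concatenate(rids))


def motif_offsets_nco(
    events: Iterable[RecombinationEvent],
    motifs: MotifSet,
    chrom_of: Mapping[str, str] | str = "chrS",
    search_flank: int = 20_000,
) -> OffsetDistribution:
    """Converted-marker offsets of NCO events relative to the nearest motif.

    Converted markers localise the tract much more tightly than the CO
    interval; each converted marker carries weight 1/k for a read with
    k converted markers.  The motif search extends ``search_flank`` bp
    around the converted span.
    """
    offs, wts, rids = [], [], []
    for ev in events:
        if ev.event_class != "NCO" or not ev.converted_positions:
            continue
        chrom = chrom_of if isinstance(chrom_of, str) else chrom_of[ev.read_id]
        lo = min(ev.converted_positions)
        hi = max(ev.converted_positions) + 1
        hit = motifs.nearest_oriented(chrom, lo - search_flank, hi + search_flank)
        if hit is None:
            continue
        pos = np.asarray(ev.converted_positions)
        off = _oriented_offset(pos, int(hit["center"]), hit["strand"])
        offs.append(off)
        wts.append(np.full(off.size, 1.0 / off.size))
        rids.append(np.full(off.size, ev.read_id, dtype=object))
    if not offs:
        return OffsetDistribution(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    return OffsetDistribution(np.concatenate(offs), np.concatenate(wts),
                              np.concatenate(rids))


def overlap_fractions(
    spans: Mapping[str, tuple[int, int]],
    motifs: MotifSet,
    inner_intervals: Mapping[str, tuple[int, int]] | None = None,
    chrom: str = "chrS",
) -> dict[str, float]:
    """Motif-overlap fractions of a read or event set.

    ``spans`` maps read id -> full span; the first fraction is the share
    of spans overlapping >= 1 motif.  If ``inner_intervals`` gives the
    event-localisation interval (CO interval, or NCO flanking-marker
    interval), the second fraction is, among overlapping reads, the
    share whose nearest motif centre falls inside it.
    """
    n = len(spans)
    if n == 0:
        return {"overlap_fraction": 0.0, "center_inside_fraction": float("nan"), "n": 0}
    n_overlap = 0
    n_inside = 0
    for rid, (a, b) in spans.items():
        hit = motifs.nearest_oriented(chrom, a, b)
        if hit is None:
            continue
        n_overlap += 1
        if inner_intervals is not None and rid in inner_intervals:
            lo, hi = inner_intervals[rid]
            if lo <= int(hit["center"]) < hi:
                n_inside += 1
    return {
        "overlap_fraction": n_overlap / n,
        "center_inside_fraction": (n_inside / n_overlap) if n_overlap else float("nan"),
        "n": n,
    }


def telomere_distances(
    event_positions: Sequence[int],
    chrom_length: int,
    read_marker_positions: Iterable[Sequence[int]],
    gmap: GeneticMap,
    chrom: str = "chrS",
    max_distance: int = 20_000_000,
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Observed vs expected histograms of distance to the nearest telomere.

    Observed: min(pos, length - pos) for each event within
    ``max_distance`` of a chromosome end.  Expected: each read
    distributes one unit of probability over its inter-marker intervals
    in proportion to their genetic-map length (an event is detected on a
    read in proportion to the local CO rate), then the mass is
    histogrammed by the interval midpoint's telomere distance.
    """
    edges = np.arange(0, max_distance + bin_size, bin_size)
    obs_d = np.asarray([min(p, chrom_length - p) for p in event_positions])
    obs_d = obs_d[obs_d < max_distance]
    obs_hist, _ = np.histogram(obs_d, bins=edges)
    exp_hist = np.zeros(edges.size - 1)
    for pos in read_marker_positions:
        x = np.asarray(pos, dtype=np.int64)
        if x.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MapBoundsWarning)
            cm = gmap.cm_at(chrom, x)
        seg_cm = np.diff(cm)
        tot = seg_cm.sum()
        if tot <= 0:
            continue
        mids = (x[:-1] + x[1:]) / 2.0
        d = np.minimum(mids, chrom_length - mids)
        sel = d < max_distance
        if not np.any(sel):
            continue
        h, _ = np.histogram(d[sel], bins=edges, weights=seg_cm[sel] / tot)
        exp_hist += h
    if exp_hist.sum() > 0 and obs_hist.sum() > 0:
        exp_scaled = exp_hist * (obs_hist.sum() / exp_hist.sum())
    else:
        exp_scaled = exp_hist
    return pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "observed": obs_hist,
        "expected": exp_scaled,
    })
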