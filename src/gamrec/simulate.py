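"""Synthetic gamete reads with planted recombination events.

The generator emulates the observable structure of a single-sperm
long-read experiment: a diploid donor with heterozygous markers at known
positions, CCS-like reads sampled from one gamete haplotype each, and
rare crossover (CO), non-crossover (NCO) and complex events that flip
the haplotype-of-origin of subsets of each read's markers.  Base-level
sequence is never simulated; the unit of observation is the per-read
marker table (position, haplotype label, base quality), plus optional
alignment-operation fixtures for exercising the read-partition filters.

Event placement follows exactly the likelihood model in
:mod:`gamrec.tractfit` (same event window, same per-read event
probability ``rho * W``, same geometric tract mixture), so that fitting
the model to its own simulations is an exact self-consistency check.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tractfit import DEFAULT_WINDOW_PAD, MarkerReadRecord, InvalidParameterError

__all__ = [
    "PlatformProfile",
    "PLATFORM_PROFILES",
    "SimulationConfig",
    "MarkerMap",
    "TrueEvent",
    "SimulatedReadRecord",
    "build_marker_map",
    "draw_tract_length",
    "simulate_reads",
    "simulate_motifs",
    "emit_alignment_pair",
    "records_from_reads",
    "marker_table",
    "truth_table",
]

_BASES = np.array(list("ACGT"))
_STRONG = frozenset("GC")


@dataclass(frozen=True)
class PlatformProfile:
    """Platform-specific QC thresholds and the binned base-quality model.

    ``bq_high``/``end_high`` gate high-confidence markers (used for
    candidate detection); ``bq_class``/``end_class`` gate the looser
    classification tier.  ``bq_bins`` are (BQ value, probability) pairs
    emitted by the simulator; ``error_rate_by_bq`` maps each emitted BQ
    value to a per-marker label-flip probability.
    """

    name: str
    bq_high: int
    end_high: int
    bq_class: int = 30
    end_class: int = 500
    bq_bins: tuple[tuple[int, float], ...] = ((93, 0.85), (40, 0.15))
    error_rate_by_bq: tuple[tuple[int, float], ...] = ((93, 0.0), (40, 2e-3))

    def tier(self, bq: int, end_distance: int) -> str | None:
        if bq >= self.bq_high and end_distance >= self.end_high:
            return "high"
        if bq >= self.bq_class and end_distance >= self.end_class:
            return "class"
        return None


PLATFORM_PROFILES: dict[str, PlatformProfile] = {
    "sequel": PlatformProfile(
        name="sequel", bq_high=60, end_high=1500, bq_class=30, end_class=500,
        bq_bins=((93, 0.85), (40, 0.15)),
        error_rate_by_bq=((93, 0.0), (40, 2e-3)),
    ),
    "revio": PlatformProfile(
        name="revio", bq_high=40, end_high=400, bq_class=30, end_class=200,
        bq_bins=((54, 0.85), (35, 0.15)),
        error_rate_by_bq=((54, 0.0), (35, 2e-3)),
    ),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe the validation-scale study: reads of mean length
    21,778 bp carrying ~10 markers each (marker rate 4.5e-4/bp), event
    parameters at the published sperm-data maximum-likelihood estimates
    (q = 14.2% COs, tract mixture m = 1.8%, L1 = 34.6 bp,
    L2 = 7,214.1 bp), and an event rate giving a detected event set of
    useful size at a few 10^5 reads while keeping ``rho * W < 1`` for
    every read.
    """

    genome_length: int = 30_000_000
    marker_rate: float = 4.5e-4
    read_length_mean: float = 21_778.0
    read_length_sd: float = 4_000.0
    read_length_min: float = 2_000.0
    n_reads: int = 50_000
    event_rate_rho: float = 3.2e-6
    co_fraction_q: float = 0.142
    mixture_weight_m: float = 0.018
    tract_mean_L1: float = 34.6
    tract_mean_L2: float = 7_214.1
    complex_rate: float = 0.0
    window_pad: int = DEFAULT_WINDOW_PAD
    platform_profile: str = "sequel"
    bq_bins: tuple[tuple[int, float], ...] | None = None
    error_rate_by_bq: tuple[tuple[int, float], ...] | None = None
    motif_density: float = 1.0 / 150_000.0
    motif_offset_shift: int = 0
    chrom: str = "chrS"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("co_fraction_q", "mixture_weight_m", "complex_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0,1], got {v}")
        if self.tract_mean_L1 < 1 or self.tract_mean_L2 < 1:
            raise InvalidParameterError("tract means must be >= 1 bp")
        if self.tract_mean_L1 > self.tract_mean_L2:
            self.tract_mean_L1, self.tract_mean_L2 = (
                self.tract_mean_L2, self.tract_mean_L1)
            self.mixture_weight_m = 1.0 - self.mixture_weight_m
        if self.genome_length <= 0:
            raise InvalidParameterError("genome_length must be positive")
        if self.genome_length <= self.read_length_mean:
            raise InvalidParameterError("genome_length must exceed mean read length")
        if self.event_rate_rho < 0:
            raise InvalidParameterError("event_rate_rho must be >= 0")
        if self.platform_profile not in PLATFORM_PROFILES:
            raise InvalidParameterError(
                f"unknown platform profile {self.platform_profile!r}")

    @property
    def profile(self) -> PlatformProfile:
        base = PLATFORM_PROFILES[self.platform_profile]
        if self.bq_bins is None and self.error_rate_by_bq is None:
            return base
        return dataclasses.replace(
            base,
            bq_bins=self.bq_bins or base.bq_bins,
            error_rate_by_bq=self.error_rate_by_bq or base.error_rate_by_bq,
        )

    @classmethod
    def tract_study(cls, n_reads: int = 200_000, **kw) -> "SimulationConfig":
        """Conditions for the tract-length recovery study.

        Emulates the post-QC marker set the likelihood consumes: every
        marker is a high-confidence call and carries no residual label
        error, matching the fitting model's assumption that sequencing
        error has been removed by the upstream filters.
        """
        kw.setdefault("bq_bins", ((93, 1.0),))
        kw.setdefault("error_rate_by_bq", ((93, 0.0),))
        return cls(n_reads=n_reads, **kw)


@dataclass
class MarkerMap:
    """Heterozygous marker positions and allele pairs on one chromosome."""

    chrom: str
    positions: np.ndarray           # sorted, strictly increasing, 0-based bp
    h1_alleles: np.ndarray          # single characters
    h2_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if np.any(self.h1_alleles == self.h2_alleles):
            raise ValueError("alleles must differ between haplotypes")

    @property
    def n(self) -> int:
        return int(self.positions.size)

    def strong_weak(self) -> np.ndarray:
        """Per-marker 'S'/'W' annotation of the haplotype-1 allele."""
        return np.where(np.isin(self.h1_alleles, list(_STRONG)), "S", "W")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": self.positions,
            "h1_allele": self.h1_alleles,
            "h2_allele": self.h2_alleles,
            "h1_sw": self.strong_weak(),
        })


@dataclass
class TrueEvent:
    """Ground truth for one read's planted event."""

    event_class: str = "none"       # none | CO | NCO | complex
    breakpoint: int = -1            # CO
    tract_start: int = -1           # NCO / complex (first segment start)
    tract_end: int = -1
    component: str = ""             # short | long (NCO)
    converted_indices: tuple[int, ...] = ()


@dataclass
class SimulatedReadRecord:
    """One simulated read: markers, true and observed labels, truth."""

    read_id: str
    chrom: str
    window_start: int
    window_end: int
    marker_positions: np.ndarray
    true_background: int
    true_labels: np.ndarray
    observed_labels: np.ndarray
    bq: np.ndarray
    truth: TrueEvent

    @property
    def n_markers(self) -> int:
        return int(self.marker_positions.size)


def build_marker_map(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    """Draw a marker map with geometric inter-marker gaps.

    Gap law: independent Geometric(marker_rate) draws on {1, 2, ...}, so
    marker counts are close to Poisson(rate * genome_length) and mean
    spacing is ~1/rate.  Allele pairs are uniform over the 12 ordered
    unequal base pairs.
    """
    if config.marker_rate <= 0:
        raise InvalidParameterError("marker_rate must be > 0")
    G = int(config.genome_length)
    n_expect = int(config.marker_rate * G * 1.05) + 100
    gaps = rng.geometric(config.marker_rate, size=n_expect)
    pos = np.cumsum(gaps) - 1
    while pos.size and pos[-1] < G - 1:
        more = rng.geometric(config.marker_rate, size=1000)
        pos = np.concatenate([pos, pos[-1] + 1 + np.cumsum(more) - 1])
    pos = pos[pos < G]
    h1 = rng.integers(0, 4, size=pos.size)
    h2 = (h1 + rng.integers(1, 4, size=pos.size)) % 4
    return MarkerMap(
        chrom=config.chrom,
        positions=pos,
        h1_alleles=_BASES[h1],
        h2_alleles=_BASES[h2],
    )


def draw_tract_length(
    m: float,
    L1: float,
    L2: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw NCO tract lengths from the two-component geometric mixture.

    With probability ``m`` the length is Geometric(mean L2) on {1,2,...},
    otherwise Geometric(mean L1); P(l >= t) = (1 - 1/L)**(t-1).
    Returns (lengths, is_long).
    """
    if L1 < 1 or L2 < 1:
        raise InvalidParameterError("mean tract lengths must be >= 1")
    if not 0.0 <= m <= 1.0:
        raise InvalidParameterError("mixture weight must be in [0,1]")
    scalar = size is None
    k = 1 if scalar else int(size)
    is_long = rng.random(k) < m
    out = np.empty(k, dtype=np.int64)
    n_long = int(is_long.sum())
    if k - n_long:
        out[~is_long] = rng.geometric(1.0 / L1, size=k - n_long)
    if n_long:
        out[is_long] = rng.geometric(1.0 / L2, size=n_long)
    if scalar:
        return int(out[0]), bool(is_long[0])
    return out, is_long


def _read_lengths(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated-normal read lengths (redrawn outside the bounds)."""
    lo = config.read_length_min
    hi = config.read_length_mean + 4.0 * config.read_length_sd
    out = rng.normal(config.read_length_mean, config.read_length_sd, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(config.read_length_mean, config.read_length_sd,
                              size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out.astype(np.int64)


def simulate_reads(
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    force_event: bool = False,
) -> list[SimulatedReadRecord]:
    """Simulate reads with at-most-one planted event each.

    Per read: background haplotype Bernoulli(1/2); an event occurs with
    probability ``rho * W`` where ``W = x_n - x_1 + pad + 1`` is the
    extended marker window (``force_event=True`` forces one on every
    read with markers, for targeted tests).  The event is complex with
    probability ``complex_rate``, else CO with probability ``q``, else
    NCO with a mixture-geometric tract.  Observation noise then flips
    each marker's label with the error rate of its base-quality bin.
    """
    profile = config.profile
    pad = int(config.window_pad)
    rho = config.event_rate_rho
    q = config.co_fraction_q
    cx = config.complex_rate
    bq_vals = np.array([b for b, _ in profile.bq_bins], dtype=np.int64)
    bq_probs = np.array([p for _, p in profile.bq_bins], dtype=np.float64)
    if abs(bq_probs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("bq bin probabilities must sum to 1")
    err_by_bq = dict(profile.error_rate_by_bq)
    err_vals = np.array([err_by_bq.get(int(b), 0.0) for b in bq_vals])

    n = int(config.n_reads)
    lengths = _read_lengths(config, rng, n)
    starts = rng.integers(0, config.genome_length - lengths + 1)
    backgrounds = 1 + rng.integers(0, 2, size=n)
    u_event = rng.random(n)

    pos_all = marker_map.positions
    reads: list[SimulatedReadRecord] = []
    for r in range(n):
        ws = int(starts[r])
        we = ws + int(lengths[r])
        i0, i1 = np.searchsorted(pos_all, (ws, we))
        x = pos_all[i0:i1]
        nm = x.size
        bg = int(backgrounds[r])
        true_labels = np.full(nm, bg, dtype=np.int8)
        truth = TrueEvent()
        if nm > 0:
            W = int(x[-1] - x[0]) + pad + 1
            lam = rho * W
            if lam >= 1.0:
                raise InvalidParameterError(
                    f"rho * window = {lam:.3g} >= 1 on read {r}")
            if force_event or u_event[r] < lam:
                c = rng.random()
                flip = np.zeros(nm, dtype=bool)
                w_lo, w_hi = int(x[0]) - pad, int(x[-1]) + 1
                if c < cx:
                    s = int(rng.integers(w_lo, w_hi))
                    nseg = int(3 + rng.integers(0, 3))
                    seg_lens = rng.geometric(1.0 / config.tract_mean_L1, size=nseg)
                    p0 = s
                    conv_state = True
                    for sl in seg_lens:
                        if conv_state:
                            flip |= (x >= p0) & (x < p0 + sl)
                        p0 += int(sl)
                        conv_state = not conv_state
                    truth = TrueEvent(
                        event_class="complex", tract_start=s, tract_end=p0,
                        converted_indices=tuple(np.flatnonzero(flip).tolist()),
                    )
                elif c < cx + (1.0 - cx) * q:
                    b = int(rng.integers(w_lo, w_hi))
                    flip = x >= b
                    truth = TrueEvent(
                        event_class="CO", breakpoint=b,
                        converted_indices=tuple(np.flatnonzero(flip).tolist()),
                    )
                else:
                    s = int(rng.integers(w_lo, w_hi))
                    ell, is_long = draw_tract_length(
                        config.mixture_weight_m, config.tract_mean_L1,
                        config.tract_mean_L2, rng)
                    flip = (x >= s) & (x < s + ell)
                    truth = TrueEvent(
                        event_class="NCO", tract_start=s, tract_end=s + ell,
                        component="long" if is_long else "short",
                        converted_indices=tuple(np.flatnonzero(flip).tolist()),
                    )
                true_labels[flip] = 3 - bg
        # observation noise by base-quality bin
        bq_idx = rng.choice(bq_vals.size, size=nm, p=bq_probs)
        bq = bq_vals[bq_idx]
        observed = true_labels.copy()
        if nm:
            err = err_vals[bq_idx]
            flips = rng.random(nm) < err
            observed[flips] = 3 - observed[flips]
        reads.append(SimulatedReadRecord(
            read_id=f"read{r:07d}",
            chrom=config.chrom,
            window_start=ws,
            window_end=we,
            marker_positions=x,
            true_background=bg,
            true_labels=true_labels,
            observed_labels=observed,
            bq=bq,
            truth=truth,
        ))
    return reads


def simulate_motifs(
    config: SimulationConfig,
    rng: np.random.Generator,
    event_positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """A BED6-style table of 31-bp hotspot motifs.

    Background motifs are placed as a Poisson process at
    ``motif_density``; if ``event_positions`` is given, one extra motif
    is planted per event with its centre displaced by
    ``motif_offset_shift`` bp in the motif's orientation (a signed shift
    plants the offset asymmetry the offset analyses look for).
    """
    G = int(config.genome_length)
    n_bg = rng.poisson(config.motif_density * G)
    centers = np.sort(rng.integers(16, G - 16, size=n_bg))
    strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
    rows = [centers, strands]
    if event_positions is not None and len(event_positions):
        ev = np.asarray(event_positions, dtype=np.int64)
        st = np.where(rng.random(ev.size) < 0.5, "+", "-")
        shift = int(config.motif_offset_shift)
        c = np.where(st == "+", ev - shift, ev + shift)
        c = np.clip(c, 16, G - 16)
        centers = np.concatenate([centers, c])
        strands = np.concatenate([strands, st])
    order = np.argsort(centers, kind="stable")
    centers, strands = centers[order], strands[order]
    return pd.DataFrame({
        "chrom": config.chrom,
        "start": centers - 15,
        "end": centers + 16,
        "name": [f"motif{i}" for i in range(centers.size)],
        "score": 0,
        "strand": strands,
    })


# ---------------------------------------------------------------------------
# Alignment-operation fixtures


def emit_alignment_pair(
    read: SimulatedReadRecord,
    softclip: int = 0,
    n_errors: int = 0,
    rng: np.random.Generator | None = None,
    default_bq: int = 93,
):
    """Alignment-operation lists for the read against both haplotypes.

    With no corruption, running the partition machinery on the result
    recovers exactly the read's markers and labels.  ``softclip`` bp of
    soft clipping (prepended, haplotype 2) and ``n_errors`` double
    mismatches (bases mismatching both haplotypes) can be planted to
    exercise the read filters.

    Returns ``(ops_h1, ops_h2, base_bq)`` where each op list holds
    ``(kind, length)`` tuples and ``base_bq`` is the per-read-base
    quality array.
    """
    L = read.window_end - read.window_start
    # per-base states: 0 match, 1 mismatch
    mm1 = np.zeros(L, dtype=np.int8)
    mm2 = np.zeros(L, dtype=np.int8)
    base_bq = np.full(L, default_bq, dtype=np.int64)
    rel = read.marker_positions - read.window_start
    lab = read.observed_labels
    mm1[rel[lab == 2]] = 1
    mm2[rel[lab == 1]] = 1
    base_bq[rel] = read.bq
    if n_errors:
        free = np.setdiff1d(np.arange(L), rel)
        if rng is None:
            step = max(len(free) // (n_errors + 1), 1)
            picks = free[step - 1 :: step][:n_errors]
        else:
            picks = rng.choice(free, size=n_errors, replace=False)
        mm1[picks] = 1
        mm2[picks] = 1

    def rle(mm: np.ndarray, clip: int) -> list[tuple[str, int]]:
        ops: list[tuple[str, int]] = []
        if clip:
            ops.append(("softclip", clip))
        arr = mm[clip:]
        if arr.size:
            edges = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], edges, [arr.size]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                ops.append(("mismatch" if arr[a] else "match", int(b - a)))
        return ops

    return rle(mm1, 0), rle(mm2, softclip), base_bq


# ---------------------------------------------------------------------------
# Tables and records


def marker_table(
    reads: Iterable[SimulatedReadRecord],
    profile: PlatformProfile,
    drop_untierable: bool = True,
) -> pd.DataFrame:
    """Long-format marker table (one row per read-marker) with QC tiers.

    The tier reflects the platform's BQ and read-end-distance rules;
    markers passing neither tier are dropped unless ``drop_untierable``
    is false (then tier is empty).
    """
    rows = {k: [] for k in ("read_id", "chrom", "window_start", "window_end",
                            "pos", "label", "bq", "tier")}
    for rd in reads:
        for p, lab, bq in zip(rd.marker_positions, rd.observed_labels, rd.bq):
            end_dist = int(min(p - rd.window_start, rd.window_end - 1 - p))
            tier = profile.tier(int(bq), end_dist)
            if tier is None and drop_untierable:
                continue
            rows["read_id"].append(rd.read_id)
            rows["chrom"].append(rd.chrom)
            rows["window_start"].append(rd.window_start)
            rows["window_end"].append(rd.window_end)
            rows["pos"].append(int(p))
            rows["label"].append(int(lab))
            rows["bq"].append(int(bq))
            rows["tier"].append(tier or "")
    return pd.DataFrame(rows)


def truth_table(reads: Iterable[SimulatedReadRecord]) -> pd.DataFrame:
    """Ground-truth event table (one row per read)."""
    rows = []
    for rd in reads:
        t = rd.truth
        rows.append((rd.read_id, t.event_class, t.breakpoint, t.tract_start,
                     t.tract_end, t.component,
                     ",".join(map(str, t.converted_indices))))
    return pd.DataFrame(rows, columns=[
        "read_id", "event_class", "breakpoint", "tract_start", "tract_end",
        "component", "converted_indices"])


def records_from_reads(
    reads: Iterable[SimulatedReadRecord],
    min_markers: int = 3,
) -> list[MarkerReadRecord]:
    """Marker records for tract fitting (observed labels, all markers)."""
    out = []
    for rd in reads:
        if rd.n_markers >= min_markers:
            out.append(MarkerReadRecord(
                read_id=rd.read_id,
                positions=rd.marker_positions,
                labels=rd.observed_labels,
            ))
    return out
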