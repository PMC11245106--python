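"""Event classification from per-read haplotype label strings.

A candidate recombinant read is one whose retained markers are not all
assigned to the same haplotype.  Classification looks only at the
switch structure of the label string:

* 0 switches: ``consistent`` (not a candidate);
* 1 switch with at least two markers on each side: ``CO``;
* 1 switch otherwise: ``ambiguous`` (CO and short NCO indistinguishable);
* 2 switches: ``NCO`` (the interior minority run is the converted tract);
* >= 3 switches: ``complex`` (patchy mismatch repair; not resolved further).

Two read-level artefact filters rest on the premise that every true
event is private to one read: transition pairs (adjacent markers
on different haplotypes) recurring at the same haplotype coordinates
across reads indicate phasing/assembly errors, and transition pairs
whose spanned interval is not covered by >= 3 reads per haplotype are
unreliable.  Classification optionally re-scores label strings on the
union of high-confidence and classification-tier markers to improve
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecombinationEvent",
    "classify_pattern",
    "n_switches",
    "classify_read",
    "recurrence_filter",
    "transition_coverage_filter",
    "haplotype_coverage",
    "summarize",
]


def n_switches(labels: str | Sequence[int]) -> int:
    arr = np.asarray(list(labels) if isinstance(labels, str) else labels)
    if arr.size == 0:
        raise ValueError("empty label string")
    return int(np.count_nonzero(arr[1:] != arr[:-1]))


def classify_pattern(labels: str | Sequence[int]) -> str:
    """Event class of a label pattern over {1,2}.

    >>> classify_pattern("1122"), classify_pattern("121"), classify_pattern("12")
    ('CO', 'NCO', 'ambiguous')
    """
    arr = np.asarray([int(c) for c in labels] if isinstance(labels, str) else labels)
    if arr.size == 0:
        raise ValueError("empty label string")
    if not np.all(np.isin(arr, (1, 2))):
        raise ValueError("labels must be 1 or 2")
    sw = np.flatnonzero(arr[1:] != arr[:-1])
    if sw.size == 0:
        return "consistent"
    if sw.size == 1:
        k = sw[0] + 1
        return "CO" if k >= 2 and arr.size - k >= 2 else "ambiguous"
    if sw.size == 2:
        return "NCO"
    return "complex"


@dataclass
class RecombinationEvent:
    """A classified read-level event with its transition coordinates."""

    read_id: str
    sample_id: str
    event_class: str
    n_switches: int
    labels: str
    # reference coordinates of the markers flanking each switch
    transitions: tuple[tuple[int, int], ...] = ()
    converted_positions: tuple[int, ...] = ()      # NCO: interior-run markers
    detectable_start: int = -1                     # 2nd marker
    detectable_end: int = -1                       # 2nd-to-last marker
    filtered: str | None = None                    # recurrence / coverage reason


def classify_read(
    read_id: str,
    positions: Sequence[int],
    labels: Sequence[int],
    sample_id: str = "",
    tiers: Sequence[str] | None = None,
) -> RecombinationEvent:
    """Classify one read from its retained markers.

    Candidacy is assessed on high-confidence markers only; if ``tiers``
    is given, the final switch structure is re-scored on the union of
    high- and classification-tier markers (which may change the class,
    e.g. an ambiguous high-tier "12" becoming a supported "1122").
    """
    pos = np.asarray(positions, dtype=np.int64)
    lab = np.asarray(labels, dtype=np.int64)
    if pos.size == 0:
        raise ValueError(f"read {read_id} has no markers")
    if tiers is not None:
        tiers = np.asarray(tiers)
        hi = tiers == "high"
        if not np.any(hi):
            raise ValueError(f"read {read_id} has no high-confidence markers")
        # candidate iff high-tier markers are not all one haplotype;
        # non-candidates are consistent regardless of class-tier markers
        if np.all(lab[hi] == lab[hi][0]):
            lab_use, pos_use = lab[hi], pos[hi]
        else:
            lab_use, pos_use = lab, pos
    else:
        lab_use, pos_use = lab, pos
    cls = classify_pattern(lab_use)
    sw = np.flatnonzero(lab_use[1:] != lab_use[:-1])
    transitions = tuple((int(pos_use[i]), int(pos_use[i + 1])) for i in sw)
    converted: tuple[int, ...] = ()
    if cls == "NCO":
        converted = tuple(int(p) for p in pos_use[sw[0] + 1: sw[1] + 1])
    ev = RecombinationEvent(
        read_id=read_id, sample_id=sample_id, event_class=cls,
        n_switches=int(sw.size), labels="".join(map(str, lab_use)),
        transitions=transitions, converted_positions=converted,
    )
    if pos_use.size >= 4:
        ev.detectable_start = int(pos_use[1])
        ev.detectable_end = int(pos_use[-2])
    return ev


def recurrence_filter(events: Sequence[RecombinationEvent]) -> list[RecombinationEvent]:
    """Drop all reads sharing a transition-pair coordinate key.

    A transition between the same two haplotype coordinates in two (or
    more) different reads is a phasing/assembly-error signature, since a
    true event is private to a single read; every read carrying a
    shared key is removed.  Idempotent.
    """
    counts: dict[tuple[int, int], set[str]] = {}
    for ev in events:
        for t in ev.transitions:
            counts.setdefault(t, set()).add(ev.read_id)
    shared = {t for t, readers in counts.items() if len(readers) > 1}
    out = []
    for ev in events:
        if any(t in shared for t in ev.transitions):
            ev.filtered = "recurrent_transition"
        else:
            out.append(ev)
    return out


def haplotype_coverage(
    read_windows: Mapping[str, tuple[int, int]],
    read_hap_consistency: Mapping[str, tuple[float, float]],
    genome_length: int,
    min_consistency: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base counts of reads >min_consistency consistent with each haplotype.

    Difference-array accumulation over read windows; used both by the
    SNV coverage-support rule and the transition coverage filter.
    """
    d1 = np.zeros(genome_length + 1, dtype=np.int32)
    d2 = np.zeros(genome_length + 1, dtype=np.int32)
    for rid, (a, b) in read_windows.items():
        c1, c2 = read_hap_consistency[rid]
        if c1 > min_consistency:
            d1[a] += 1
            d1[b] -= 1
        if c2 > min_consistency:
            d2[a] += 1
            d2[b] -= 1
    return np.cumsum(d1[:-1]), np.cumsum(d2[:-1])


def transition_coverage_filter(
    events: Sequence[RecombinationEvent],
    coverage_h1: np.ndarray,
    coverage_h2: np.ndarray,
    min_coverage: int = 3,
) -> list[RecombinationEvent]:
    """Keep events whose transition gaps are well covered on both haplotypes.

    Every base strictly between each transition pair must be covered by
    at least ``min_coverage`` reads on each haplotype; a zero-length gap
    (adjacent bases) passes vacuously.
    """
    out = []
    for ev in events:
        ok = True
        for a, b in ev.transitions:
            lo, hi = a + 1, b  # strictly between the two markers
            if lo >= hi:
                continue
            if (np.min(coverage_h1[lo:hi]) < min_coverage
                    or np.min(coverage_h2[lo:hi]) < min_coverage):
                ok = False
                break
        if ok:
            out.append(ev)
        else:
            ev.filtered = "low_coverage_transition"
    return out


def summarize(
    events: Iterable[RecombinationEvent],
    exclude: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample event counts and NCO tract summaries.

    Returns a table with one row per sample plus a totals row, and a
    dict with the single-marker NCO fraction (fraction of NCO reads
    whose tract converts exactly one marker).  ``exclude`` lists read
    ids removed by manual curation.
    """
    excluded = set(exclude)
    classes = ("CO", "NCO", "ambiguous", "complex")
    per: dict[str, dict[str, int]] = {}
    n_nco = 0
    n_single = 0
    for ev in events:
        if ev.read_id in excluded or ev.filtered is not None:
            continue
        if ev.event_class not in classes:
            continue
        row = per.setdefault(ev.sample_id, {c: 0 for c in classes})
        row[ev.event_class] += 1
        if ev.event_class == "NCO":
            n_nco += 1
            if len(ev.converted_positions) == 1:
                n_single += 1
    table = pd.DataFrame(
        [{"sample": s, **row} for s, row in sorted(per.items())],
        columns=["sample", *classes],
    )
    totals = {c: int(table[c].sum()) if len(table) else 0 for c in classes}
    table.loc[len(table)] = {"sample": "Totals", **totals}
    frac = n_single / n_nco if n_nco else float("nan")
    return table, {
        "n_nco": n_nco,
        "n_single_marker": n_single,
        "single_marker_fraction": frac,
    }
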