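"""Candidate-read generation: joint alignment partition and SNV filters.

A gamete read is aligned separately to the donor's two assembled
haplotypes.  Each alignment partitions the read into segments labelled
by alignment operation (match, mismatch, insertion, deletion, soft
clip); intersecting the two partitions yields the *refined partition*,
in which every read segment carries one operation per haplotype.
Single-base segments that match one haplotype and mismatch the other
are candidate SNVs; a cascade of quality filters (flanking match,
read-end distance, base quality, low-complexity and tandem-repeat
masks, haplotype read coverage) then selects the markers used for
recombination detection, and the per-read string of haplotype labels is
the input to event classification.

This module operates on alignment-operation lists (e.g. produced by the
simulator's fixture emitter or parsed from compact "40M 1X 9M" text);
real BAM ingestion and upstream alignment QC (MAPQ, primary-alignment
selection, strand/chromosome concordance) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import PlatformProfile

__all__ = [
    "OP_KINDS",
    "MalformedAlignmentError",
    "RefinedSegment",
    "CandidateSNV",
    "parse_ops",
    "refine_partition",
    "read_filters",
    "detect_and_filter_snvs",
    "coverage_support",
    "haplotype_string",
    "read_bed3",
    "mask_intervals",
]

OP_KINDS = ("match", "mismatch", "insertion", "deletion", "softclip")
#: read bases consumed per op kind (deletion consumes none)
_CONSUMES_READ = {"match": True, "mismatch": True, "insertion": True,
                  "deletion": False, "softclip": True}
#: reference bases consumed per op kind
_CONSUMES_REF = {"match": True, "mismatch": True, "insertion": False,
                 "deletion": True, "softclip": False}

_CODE_TO_KIND = {"M": "match", "=": "match", "X": "mismatch", "I": "insertion",
                 "D": "deletion", "S": "softclip"}


class MalformedAlignmentError(ValueError):
    """Op lists inconsistent with the stated read length."""


def parse_ops(text: str) -> list[tuple[str, int]]:
    """Parse compact op text like ``"40M 1X 9M"`` into (kind, length) pairs."""
    ops = []
    for tok in text.split():
        kind = _CODE_TO_KIND.get(tok[-1])
        if kind is None:
            raise MalformedAlignmentError(f"unknown op code in {tok!r}")
        ops.append((kind, int(tok[:-1])))
    return ops


@dataclass
class RefinedSegment:
    """A read interval [start, end) with one alignment op per haplotype.

    ``ref1``/``ref2`` are the reference positions (per haplotype) of the
    segment start; deletions appear as zero-length read intervals.
    """

    start: int
    end: int
    op1: str
    op2: str
    ref1: int
    ref2: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateSNV:
    """A single-base site matching one haplotype and mismatching the other."""

    read_id: str
    read_pos: int
    hap_matched: int                # 1 or 2
    bq: int
    ref1: int
    ref2: int
    flank_left: int = 0             # bp of match-to-both flank on each side
    flank_right: int = 0
    end_distance: int = 0
    tier: str = ""
    reject_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.reject_reason is None


def _op_breaks(ops: Sequence[tuple[str, int]], read_length: int):
    """Per-op (read_start, read_end, kind, ref_start) with validation."""
    out = []
    rpos = 0
    ref = 0
    for kind, length in ops:
        if kind not in _CONSUMES_READ:
            raise MalformedAlignmentError(f"unknown op kind {kind!r}")
        if length < 0:
            raise MalformedAlignmentError("negative op length")
        rspan = length if _CONSUMES_READ[kind] else 0
        out.append((rpos, rpos + rspan, kind, ref))
        rpos += rspan
        ref += length if _CONSUMES_REF[kind] else 0
    if rpos != read_length:
        raise MalformedAlignmentError(
            f"ops consume {rpos} read bases, expected {read_length}")
    return out


def refine_partition(
    ops_h1: Sequence[tuple[str, int]],
    ops_h2: Sequence[tuple[str, int]],
    read_length: int,
) -> list[RefinedSegment]:
    """Intersect the two per-haplotype partitions of a read.

    Returns segments tiling [0, read_length); maximal runs with the same
    op pair are merged.  Deletions contribute zero-length segments that
    break merging (and flanking-match runs), mirroring their role as
    alignment discontinuities.
    """
    b1 = _op_breaks(ops_h1, read_length)
    b2 = _op_breaks(ops_h2, read_length)
    # boundary positions from both partitions
    cuts = sorted({p for seg in b1 + b2 for p in seg[:2]} | {0, read_length})
    segs: list[RefinedSegment] = []

    def covering(breaks, pos, zero_len_first: bool):
        """Op covering read position pos (non-zero-length ops only)."""
        for rs, re_, kind, ref in breaks:
            if rs <= pos < re_:
                return kind, ref + (pos - rs)
        # pos == read_length or only zero-length ops here: use last op before
        last = None
        for rs, re_, kind, ref in breaks:
            if re_ <= pos and re_ > rs:
                last = (kind, ref + (re_ - rs))
        return last if last else ("match", 0)

    # zero-length (deletion) segments, keyed by read position
    zeros: dict[int, list[tuple[int, str, int]]] = {}
    for hap, breaks in ((1, b1), (2, b2)):
        for rs, re_, kind, ref in breaks:
            if rs == re_:
                zeros.setdefault(rs, []).append((hap, kind, ref))

    for a, b in zip(cuts[:-1], cuts[1:]):
        for hap, kind, ref in zeros.get(a, []):
            other_kind, other_ref = covering(b2 if hap == 1 else b1, a, True)
            if hap == 1:
                segs.append(RefinedSegment(a, a, kind, other_kind, ref, other_ref))
            else:
                segs.append(RefinedSegment(a, a, other_kind, kind, other_ref, ref))
        k1, r1 = covering(b1, a, False)
        k2, r2 = covering(b2, a, False)
        segs.append(RefinedSegment(a, b, k1, k2, r1, r2))
    for hap, kind, ref in zeros.get(read_length, []):
        other_kind, other_ref = covering(b2 if hap == 1 else b1, read_length, True)
        if hap == 1:
            segs.append(RefinedSegment(read_length, read_length, kind, other_kind, ref, other_ref))
        else:
            segs.append(RefinedSegment(read_length, read_length, other_kind, kind, other_ref, ref))
    # merge adjacent same-pair segments (zero-length segments block merging)
    merged: list[RefinedSegment] = []
    for s in segs:
        if (merged and s.length and merged[-1].length
                and merged[-1].end == s.start
                and (merged[-1].op1, merged[-1].op2) == (s.op1, s.op2)):
            merged[-1].end = s.end
        else:
            merged.append(s)
    return merged


def read_filters(
    segments: Sequence[RefinedSegment],
    ops_h1: Sequence[tuple[str, int]],
    ops_h2: Sequence[tuple[str, int]],
    max_softclip: int = 10,
    max_errors: int = 100,
) -> tuple[bool, str | None]:
    """Whole-read QC: (keep, reason-if-discarded).

    Discards reads with more than ``max_softclip`` bp of soft clipping
    to either haplotype (chimera signature) or more than ``max_errors``
    double-mismatch segments (bases mismatching both haplotypes).
    """
    for ops in (ops_h1, ops_h2):
        clip = sum(length for kind, length in ops if kind == "softclip")
        if clip > max_softclip:
            return False, "softclip"
    n_err = sum(1 for s in segments
                if s.op1 == "mismatch" and s.op2 == "mismatch")
    if n_err > max_errors:
        return False, "errors"
    return True, None


def _flank_lengths(segments: Sequence[RefinedSegment], idx: int) -> tuple[int, int]:
    """Contiguous match-to-both flank lengths on each side of segment idx.

    Any non match/match segment -- including a zero-length deletion --
    terminates the flank.
    """
    left = 0
    for s in reversed(segments[:idx]):
        if s.op1 == "match" and s.op2 == "match" and s.length > 0:
            left += s.length
        else:
            break
    right = 0
    for s in segments[idx + 1:]:
        if s.op1 == "match" and s.op2 == "match" and s.length > 0:
            right += s.length
        else:
            break
    return left, right


def read_bed3(path) -> pd.DataFrame:
    """Plain BED3 (chrom, start, end), comment lines tolerated."""
    return pd.read_csv(path, sep="\t", comment="#", header=None,
                       usecols=[0, 1, 2], names=["chrom", "start", "end"])


def mask_intervals(bed: pd.DataFrame | None) -> list[tuple[int, int]]:
    """Sorted half-open interval list from a BED frame (single sequence)."""
    if bed is None or not len(bed):
        return []
    return sorted(zip(bed["start"].astype(int), bed["end"].astype(int)))


def _in_mask(intervals: list[tuple[int, int]], pos: int) -> bool:
    for a, b in intervals:
        if a <= pos < b:
            return True
        if a > pos:
            break
    return False


def detect_and_filter_snvs(
    segments: Sequence[RefinedSegment],
    base_bq: np.ndarray,
    profile: PlatformProfile,
    tier: str = "high",
    read_id: str = "",
    read_length: int | None = None,
    low_complexity: tuple[list, list] | None = None,
    tandem_repeat: tuple[list, list] | None = None,
    min_flank: int = 10,
) -> list[CandidateSNV]:
    """Call and filter candidate SNVs from a refined partition.

    A candidate is a 1-bp segment matching exactly one haplotype and
    mismatching the other.  Filters apply in order, the first failure
    being recorded: flanking match-to-both >= ``min_flank`` bp on each
    side; distance from both read ends (tier- and platform-specific);
    base quality (tier- and platform-specific); low-complexity and
    tandem-repeat masks in either haplotype's coordinates.
    """
    if tier == "high":
        min_bq, min_end = profile.bq_high, profile.end_high
    elif tier == "class":
        min_bq, min_end = profile.bq_class, profile.end_class
    else:
        raise ValueError(f"unknown tier {tier!r}")
    if read_length is None:
        read_length = max((s.end for s in segments), default=0)
    lc1, lc2 = low_complexity if low_complexity else ([], [])
    tr1, tr2 = tandem_repeat if tandem_repeat else ([], [])

    out: list[CandidateSNV] = []
    for idx, seg in enumerate(segments):
        pair = (seg.op1, seg.op2)
        if seg.length != 1 or "match" not in pair or "mismatch" not in pair:
            continue
        hap = 1 if seg.op1 == "match" else 2
        pos = seg.start
        snv = CandidateSNV(
            read_id=read_id, read_pos=pos, hap_matched=hap,
            bq=int(base_bq[pos]), ref1=seg.ref1, ref2=seg.ref2, tier=tier,
        )
        snv.flank_left, snv.flank_right = _flank_lengths(segments, idx)
        snv.end_distance = min(pos, read_length - 1 - pos)
        if snv.flank_left < min_flank or snv.flank_right < min_flank:
            snv.reject_reason = "flank"
        elif snv.end_distance < min_end:
            snv.reject_reason = "end_distance"
        elif snv.bq < min_bq:
            snv.reject_reason = "bq"
        elif _in_mask(lc1, seg.ref1) or _in_mask(lc2, seg.ref2):
            snv.reject_reason = "low_complexity"
        elif _in_mask(tr1, seg.ref1) or _in_mask(tr2, seg.ref2):
            snv.reject_reason = "tandem_repeat"
        out.append(snv)
    return out


def coverage_support(
    n_consistent_h1: int,
    n_consistent_h2: int,
    min_reads: int = 3,
) -> bool:
    """Assembly-support rule at a focal SNV position.

    Requires at least ``min_reads`` overlapping reads >95% consistent
    with haplotype 1 and, independently, the same for haplotype 2.
    """
    return n_consistent_h1 >= min_reads and n_consistent_h2 >= min_reads


def haplotype_string(snvs: Sequence[CandidateSNV]) -> str:
    """Per-read label string ('1'/'2' per retained SNV, in read order)."""
    kept = sorted((s for s in snvs if s.retained), key=lambda s: s.read_pos)
    return "".join(str(s.hap_matched) for s in kept)
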