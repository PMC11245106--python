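"""Statistical toolbox: permutation Anderson-Darling tests, contingency
tests, GC-bias of converted markers, and motif-offset asymmetry.

The two-sample Anderson-Darling (AD) statistic compares empirical
distribution functions with weight concentrated in the tails,

    A2 = 1/(n m) * sum_{i=1}^{N-1} (M_i N - n i)^2 / (i (N - i)),

where the pooled sample of size N = n + m is sorted, and M_i counts how
many of the i smallest pooled values came from the first sample.
Significance is always assessed by permutation: measurements are
randomly reassigned to the two samples (sizes preserved) and the
p-value is the fraction of permuted statistics at least as large as the
observed one.  For continuous (tie-free) measurements this equals the
strictly-larger count almost surely; counting ties keeps degenerate
inputs (identical constant samples) at p = 1 rather than an
artefactual 0.

The one-vs-many variant sums the pairwise AD statistics between a focal
sample and each other sample, permuting each pair independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationTestResult",
    "OffsetDistribution",
    "ad_two_sample",
    "perm_test_pair",
    "perm_test_one_vs_many",
    "fisher_exact_2x2",
    "chi2_2x2",
    "fishers_method",
    "gc_bias",
    "offset_asymmetry_test",
]

_STRONG = frozenset("GC")
_WEAK = frozenset("AT")


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def _ad_from_membership(member: np.ndarray, n: int, m: int,
                        boundary: np.ndarray | None = None) -> np.ndarray:
    """AD statistic(s) from first-sample membership in pooled sorted order.

    ``member`` is boolean with shape (..., N) where the last axis runs
    over the pooled order statistics.  ``boundary`` marks positions i
    where the i-th and (i+1)-th pooled order statistics differ: with
    ties, only those positions correspond to a point where the two
    ECDFs can actually be compared, which makes the statistic invariant
    to the ordering of tied values.  ``None`` means all-distinct.
    """
    N = n + m
    M = np.cumsum(member, axis=-1)[..., :-1]
    i = np.arange(1, N)
    num = (M * N - n * i) ** 2 / (i * (N - i))
    if boundary is not None:
        num = num * boundary
    return np.sum(num, axis=-1) / (n * m)


def _pooled(x: np.ndarray, y: np.ndarray):
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    v = pooled[order]
    boundary = v[:-1] < v[1:]
    member = np.zeros(pooled.size, dtype=bool)
    member[: x.size] = True
    return member[order], boundary


def ad_two_sample(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample Anderson-Darling statistic (permutation-test version)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    member, boundary = _pooled(x, y)
    return float(_ad_from_membership(member, x.size, y.size, boundary))


def _perm_stats_pair(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Observed AD and its permutation distribution for one sample pair."""
    n, m = x.size, y.size
    member, boundary = _pooled(x, y)
    obs = float(_ad_from_membership(member, n, m, boundary))
    # random reassignment = random membership vectors with n ones,
    # applied to the fixed pooled order
    base = np.broadcast_to(member, (n_perm, n + m))
    perm_member = rng.permuted(base, axis=1)
    return obs, _ad_from_membership(perm_member, n, m, boundary)


def perm_test_pair(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationTestResult:
    """Two-sample AD equality-of-distribution test by permutation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    obs, perm = _perm_stats_pair(x, y, n_perm, rng)
    p = float(np.mean(perm >= obs - 1e-12))
    return PermutationTestResult(statistic=obs, p_value=p, n_perm=n_perm, seed=seed)


def perm_test_one_vs_many(
    focal: Sequence[float],
    others: Sequence[Sequence[float]],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationTestResult:
    """Sum-of-AD test of one focal sample against several others.

    The statistic is sum_j AD(focal, other_j); each focal-vs-other pair
    is permuted independently and the permuted sums form the null.
    With a single other sample this reduces to ``perm_test_pair``.
    """
    if len(others) == 0:
        raise ValueError("need at least one other sample")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    focal = np.asarray(focal, dtype=np.float64)
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    obs_total = 0.0
    perm_total = np.zeros(n_perm)
    for other in others:
        other = np.asarray(other, dtype=np.float64)
        obs, perm = _perm_stats_pair(focal, other, n_perm, rng)
        obs_total += obs
        perm_total += perm
    p = float(np.mean(perm_total >= obs_total - 1e-12))
    return PermutationTestResult(statistic=obs_total, p_value=p, n_perm=n_perm,
                                 seed=seed)


# ---------------------------------------------------------------------------
# Contingency tests


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric outcomes with
    probability <= the observed one); degenerate margins give p = 1."""
    t = _check_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction."""
    t = _check_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 0.0, 1.0
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def fishers_method(p_values: Sequence[float]) -> float:
    """Combine independent p-values: -2 sum(ln p) ~ chi2 on 2k df."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0 or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(stat, df=2 * p.size))


# ---------------------------------------------------------------------------
# GC-bias


def gc_bias(
    transmitted_alleles: Sequence[str],
    partner_alleles: Sequence[str] | None = None,
    alpha: float = 0.05,
    method: str = "wald",
) -> tuple[float, tuple[float, float], int]:
    """GC-biased gene conversion among converted strong/weak markers.

    ``transmitted_alleles`` are the converted-to bases; only sites that
    are strong/weak heterozygous (one of G/C vs one of A/T, judged from
    ``partner_alleles`` when given, else from the transmitted base
    alone) qualify.  Returns (fraction transmitted strong, CI, n).
    CI: normal (Wald) approximation by default, clamped to [0,1];
    ``method="exact"`` gives Clopper-Pearson.
    """
    trans = np.asarray([a.upper() for a in transmitted_alleles])
    if partner_alleles is not None:
        part = np.asarray([a.upper() for a in partner_alleles])
        sw = np.array([
            (t in _STRONG) != (p in _STRONG)
            for t, p in zip(trans, part)
        ])
        trans = trans[sw]
    n = trans.size
    if n == 0:
        raise ValueError("no qualifying strong/weak conversions")
    k = int(np.sum(np.isin(trans, list(_STRONG))))
    frac = k / n
    if method == "wald":
        se = math.sqrt(frac * (1 - frac) / n)
        z = sps.norm.ppf(1 - alpha / 2)
        lo, hi = max(frac - z * se, 0.0), min(frac + z * se, 1.0)
    elif method == "exact":
        lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return frac, (float(lo), float(hi)), n


# ---------------------------------------------------------------------------
# Motif-offset asymmetry


@dataclass
class OffsetDistribution:
    """Signed, motif-oriented offsets with per-read weights.

    Offsets are bp relative to the motif centre, positive downstream in
    the motif's orientation.  Each source read's weights sum to 1.
    """

    offsets: np.ndarray
    weights: np.ndarray
    read_ids: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.read_ids = np.asarray(self.read_ids)
        if not (self.offsets.size == self.weights.size == self.read_ids.size):
            raise ValueError("offsets, weights, read_ids must align")
        for rid in np.unique(self.read_ids):
            s = self.weights[self.read_ids == rid].sum()
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"weights of read {rid} sum to {s}, not 1")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def downstream_fraction(self) -> float:
        """Weight fraction strictly downstream (offset > 0); half weight
        at the centre itself."""
        w = self.weights
        frac = np.sum(w * (self.offsets > 0)) + 0.5 * np.sum(w * (self.offsets == 0))
        return float(frac / w.sum())

    def weighted_mean_abs(self) -> float:
        return float(np.sum(self.weights * np.abs(self.offsets)) / self.weights.sum())

    def weighted_median(self) -> float:
        order = np.argsort(self.offsets)
        v = self.offsets[order]
        cw = np.cumsum(self.weights[order])
        half = 0.5 * cw[-1]
        idx = int(np.searchsorted(cw, half))
        idx = min(idx, v.size - 1)
        # exact half-mass split: midpoint convention
        if abs(cw[idx] - half) < 1e-12 and idx + 1 < v.size:
            return float(0.5 * (v[idx] + v[idx + 1]))
        return float(v[idx])


def offset_asymmetry_test(
    dist: OffsetDistribution,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationTestResult:
    """Sign-flip permutation test of offset asymmetry.

    The statistic is the weight fraction on the heavier side.  The null
    randomises motif orientation: each source read's offsets have their
    signs flipped together with probability 1/2.  p is the fraction of
    permuted statistics at least as large as the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    uniq, inv = np.unique(dist.read_ids, return_inverse=True)
    w = dist.weights
    tot = w.sum()
    signed = w * np.sign(dist.offsets)          # zero offsets stay neutral
    down = float(np.sum(w * (dist.offsets > 0)) + 0.5 * np.sum(w * (dist.offsets == 0)))
    obs = max(down, tot - down) / tot
    # per-read downstream weight under each orientation
    read_down = np.bincount(inv, weights=w * (dist.offsets > 0), minlength=uniq.size)
    read_zero = np.bincount(inv, weights=w * (dist.offsets == 0), minlength=uniq.size)
    read_tot = np.bincount(inv, weights=w, minlength=uniq.size)
    flips = rng.random((n_perm, uniq.size)) < 0.5
    # flipping a read turns its downstream weight d into (tot_r - zero_r - d)
    d = np.where(flips, read_tot - read_zero - read_down, read_down)
    down_p = d.sum(axis=1) + 0.5 * read_zero.sum()
    stat_p = np.maximum(down_p, tot - down_p) / tot
    p = float(np.mean(stat_p >= obs - 1e-12))
    return PermutationTestResult(statistic=obs, p_value=p, n_perm=n_perm, seed=seed)
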