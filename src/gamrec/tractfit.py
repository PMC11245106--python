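"""Likelihood inference of non-crossover (NCO) gene-conversion tract lengths.

The data are long gamete reads, each carrying a handful of heterozygous
markers assigned to one of the donor's two haplotypes.  A meiotic event
leaves a haplotype-switch signature on a read: a crossover (CO) switches
all markers downstream of its breakpoint, while an NCO converts the
markers covered by a short tract, producing an interior run of
opposite-haplotype markers.  Because reads carry few markers, most NCO
tracts convert no marker at all and are invisible; inference therefore
runs over *unascertained* reads (every QC-passing read with >= 3
markers), marginalising over unobserved events.

Generative model (per read, markers at integer positions x_1 <= ... <= x_n):

* A window of candidate event origins ``[x_1 - T, x_n + 1)`` of integer
  size ``W = x_n - x_1 + T + 1`` extends the marker span left by a pad
  ``T`` so that tracts beginning upstream of the read can still convert
  its leftmost markers.  ``T`` is a fixed model constant chosen so the
  long-component tail mass beyond it is negligible (< 1e-12 at the
  default pad for mean tract lengths up to ~7.2 kb).
* The read's background haplotype is Bernoulli(1/2).
* At most one event occurs, with probability ``lambda_r = rho * W``.
* With probability ``q`` the event is a CO: a uniform breakpoint ``b``
  in the window flips every marker at position >= b.
* Otherwise it is an NCO: a tract starts uniformly in the window and
  extends right for a geometric number of bases -- a single geometric
  law with mean ``L`` (single model), or a two-component mixture with
  weight ``m`` on the long component (means ``L1 <= L2``; mixture
  model).  Markers covered by the tract are flipped.

Sequencing error is not modelled: markers are assumed to be the
post-quality-control set.  Reads whose label pattern has three or more
switches have probability zero under the at-most-one-event model and
are excluded from fitting (they are classified separately as complex
events).

Free parameters: single model (rho, q, L) -> k = 3; mixture model
(rho, q, m, L1, L2) -> k = 5.  AIC = 2k - 2 logL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DEFAULT_WINDOW_PAD",
    "MarkerReadRecord",
    "TractModelParams",
    "FitOptions",
    "FitResult",
    "DetectionSummary",
    "truncation_length",
    "window_size",
    "nco_pattern_prob",
    "read_pattern_logprob",
    "pattern_class_probs",
    "PackedReads",
    "loglik",
    "fit_model",
    "compare_models",
    "bootstrap_ci",
    "detection_summary",
]

#: Left pad of the event-origin window, in bp.  Shared with the read
#: simulator so that simulated data follow exactly this likelihood.
DEFAULT_WINDOW_PAD = 200_000


class InvalidParameterError(ValueError):
    """Raised for parameters outside the model's domain."""


def truncation_length(L: float, tail: float = 1e-12) -> int:
    """Smallest integer T with P(tract length > T) < ``tail`` for mean ``L``."""
    if L < 1:
        raise InvalidParameterError(f"mean tract length must be >= 1, got {L}")
    if L == 1.0:
        return 1
    phi = 1.0 - 1.0 / L
    # P(l > T) = phi**T
    return int(math.ceil(math.log(tail) / math.log(phi))) + 1


def window_size(positions: Sequence[int], pad: int = DEFAULT_WINDOW_PAD) -> int:
    """Number of candidate integer event origins for a read's marker set."""
    x = np.asarray(positions)
    return int(x[-1] - x[0]) + pad + 1


# ---------------------------------------------------------------------------
# Parameters and records


@dataclass
class TractModelParams:
    """Event-process parameters.

    rho : events per bp of event window; q : CO fraction; m : weight of
    the long tract component; L1, L2 : mean tract lengths in bp with
    L1 <= L2 (swapped at construction, with m -> 1 - m, otherwise).
    """

    rho: float
    q: float
    m: float
    L1: float
    L2: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise InvalidParameterError(f"rho must be >= 0, got {self.rho}")
        for name in ("q", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0,1], got {v}")
        if self.L1 < 1 or self.L2 < 1:
            raise InvalidParameterError("mean tract lengths must be >= 1")
        if self.L1 > self.L2:
            self.L1, self.L2 = self.L2, self.L1
            self.m = 1.0 - self.m

    @classmethod
    def single(cls, rho: float, q: float, L: float) -> "TractModelParams":
        return cls(rho=rho, q=q, m=0.0, L1=L, L2=L)

    @property
    def phi1(self) -> float:
        return 1.0 - 1.0 / self.L1

    @property
    def phi2(self) -> float:
        return 1.0 - 1.0 / self.L2


@dataclass
class MarkerReadRecord:
    """A read's QC markers: sorted positions and haplotype labels (1/2)."""

    read_id: str
    positions: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.positions.ndim != 1 or self.positions.size != self.labels.size:
            raise ValueError("positions and labels must be 1-d and equal length")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("marker positions must be sorted")

    @property
    def n(self) -> int:
        return int(self.positions.size)


# ---------------------------------------------------------------------------
# Closed-form geometric masses
#
# All "mass" functions return counting-measure sums over integer tract
# starts s (not yet divided by the window size W): the probability that a
# tract starting at s, with geometric length of mean L, converts exactly a
# given marker subset, summed over the admissible s.


def _pow(phi: float, k):
    """phi**k for integer k >= 0, with the 0**0 = 1 convention."""
    k = np.asarray(k, dtype=np.float64)
    if phi <= 0.0:
        return np.where(k == 0, 1.0, 0.0)
    return np.exp(k * math.log(phi))


def _geom_sum(phi: float, a, b):
    """sum_{k=a}^{b} phi**k for integer arrays 0 <= a <= b."""
    if phi <= 0.0:
        # only the k == 0 term survives
        a = np.asarray(a)
        return np.where(a == 0, 1.0, 0.0)
    return (_pow(phi, a) - _pow(phi, np.asarray(b) + 1)) / (1.0 - phi)


def _run_mass(x: np.ndarray, i: int, j: int, L: float, pad: int) -> float:
    """Mass of tracts converting exactly the contiguous markers i..j (incl.)."""
    phi = 1.0 - 1.0 / L
    s_lo = int(x[i - 1]) + 1 if i > 0 else int(x[0]) - pad
    s_hi = int(x[i])
    # P(convert through x_j) = phi**(x_j - s); subtract reaching x_{j+1}
    lead = _geom_sum(phi, x[j] - s_hi, x[j] - s_lo)
    if j < x.size - 1:
        lead -= _geom_sum(phi, x[j + 1] - s_hi, x[j + 1] - s_lo)
    return float(lead)


def _none_mass(x: np.ndarray, L: float, pad: int) -> float:
    """Mass of tracts converting no marker at all."""
    phi = 1.0 - 1.0 / L
    # starts are binned by the first marker at or right of them
    counts = np.empty(x.size, dtype=np.int64)
    counts[0] = pad + 1
    counts[1:] = np.diff(x)
    # for each start, P(stop before its first reachable marker) = 1 - phi**d
    return float(np.sum(counts) - np.sum(_geom_sum(phi, np.zeros_like(counts), counts - 1)))


def nco_pattern_prob(
    positions: Sequence[int],
    subset: Iterable[int],
    L: float,
    pad: int = DEFAULT_WINDOW_PAD,
) -> float:
    """Probability that one NCO tract converts exactly ``subset`` of the markers.

    The tract start is uniform on the ``[x_1 - pad, x_n + 1)`` window and
    its length geometric with mean ``L``.  ``subset`` holds 0-based marker
    indices; non-contiguous subsets have probability zero.
    """
    if L < 1:
        raise InvalidParameterError(f"mean tract length must be >= 1, got {L}")
    x = np.asarray(positions, dtype=np.int64)
    if x.size == 0:
        raise ValueError("need at least one marker")
    W = window_size(x, pad)
    idx = sorted(set(int(k) for k in subset))
    if any(k < 0 or k >= x.size for k in idx):
        raise IndexError("subset index out of range")
    if not idx:
        return _none_mass(x, L, pad) / W
    i, j = idx[0], idx[-1]
    if idx != list(range(i, j + 1)):
        return 0.0
    # duplicate positions make a strict subset of a tie group unreachable
    if (i > 0 and x[i - 1] == x[i]) or (j < x.size - 1 and x[j + 1] == x[j]):
        return 0.0
    return _run_mass(x, i, j, L, pad) / W


def _mix_mass(x, i, j, params: TractModelParams, pad) -> float:
    a = _run_mass(x, i, j, params.L1, pad)
    if params.m == 0.0:
        return a
    b = _run_mass(x, i, j, params.L2, pad)
    return (1.0 - params.m) * a + params.m * b


def _mix_none(x, params: TractModelParams, pad) -> float:
    a = _none_mass(x, params.L1, pad)
    if params.m == 0.0:
        return a
    b = _none_mass(x, params.L2, pad)
    return (1.0 - params.m) * a + params.m * b


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal labels as (start, end) inclusive index pairs."""
    switches = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], switches + 1))
    ends = np.concatenate((switches, [labels.size - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def read_pattern_logprob(
    positions: Sequence[int],
    labels: Sequence[int],
    params: TractModelParams,
    pad: int = DEFAULT_WINDOW_PAD,
) -> float:
    """Log-probability of a read's observed haplotype-label vector.

    Reference (scalar) implementation; ``loglik`` evaluates the same
    quantity vectorised over packed reads.  Marginalises the background
    haplotype (1/2 each) and the unobserved event type.  Patterns with
    >= 3 switches are impossible under the at-most-one-event model and
    return ``-inf``.
    """
    x = np.asarray(positions, dtype=np.int64)
    lab = np.asarray(labels)
    n = x.size
    W = window_size(x, pad)
    lam = params.rho * W
    if lam >= 1.0:
        raise InvalidParameterError(
            f"rho * window = {lam:.3g} >= 1; event probability per read exceeds one"
        )
    q, m = params.q, params.m
    runs = _runs(lab)
    if len(runs) == 1:
        # background = observed: no event, or an event converting nothing;
        # background = flipped: an event converting everything.
        a_none = (1.0 - q) * _mix_none(x, params, pad) / W
        a_full = (q * (pad + 1) + (1.0 - q) * _mix_mass(x, 0, n - 1, params, pad)) / W
        p = 0.5 * ((1.0 - lam) + lam * a_none) + 0.5 * lam * a_full
    elif len(runs) == 2:
        k = runs[1][0]  # first index of the right run
        gap = float(x[k] - x[k - 1])
        a_suffix = (q * gap + (1.0 - q) * _mix_mass(x, k, n - 1, params, pad)) / W
        a_prefix = (1.0 - q) * _mix_mass(x, 0, k - 1, params, pad) / W
        p = 0.5 * lam * (a_suffix + a_prefix)
    elif len(runs) == 3:
        i, j = runs[1]
        p = 0.5 * lam * (1.0 - q) * _mix_mass(x, i, j, params, pad) / W
    else:
        return -math.inf
    if p <= 0.0:
        return -math.inf
    return math.log(p)


def pattern_class_probs(
    positions: Sequence[int],
    params: TractModelParams,
    pad: int = DEFAULT_WINDOW_PAD,
) -> dict[str, float]:
    """Total probability of each observable switch class for one read.

    Closed form: prefix- and suffix-run masses telescope over the shared
    start ranges, so no per-run enumeration is needed.  Keys:
    ``consistent`` (0 switches), ``one_switch``, ``two_switch``,
    ``complex`` (always 0 under this model).
    """
    x = np.asarray(positions, dtype=np.int64)
    n = x.size
    W = window_size(x, pad)
    span = float(x[-1] - x[0])
    lam = params.rho * W
    if lam >= 1.0:
        raise InvalidParameterError("rho * window >= 1")
    q = params.q

    def one_side_masses(L: float) -> tuple[float, float, float, float]:
        phi = 1.0 - 1.0 / L
        none = _none_mass(x, L, pad)
        full = _run_mass(x, 0, n - 1, L, pad)
        # sum of all proper-prefix run masses: common start range [x0-pad, x0]
        pre = float(_geom_sum(phi, 0, pad) - _geom_sum(phi, span, span + pad))
        # sum of all proper-suffix run masses: starts in (x0, x_{n-1}]
        suf = float(_geom_sum(phi, 0, span - 1)) if span >= 1 else 0.0
        return none, full, pre, suf

    n1, f1, p1, s1 = one_side_masses(params.L1)
    if params.m > 0.0:
        n2, f2, p2, s2 = one_side_masses(params.L2)
    else:
        n2 = f2 = p2 = s2 = 0.0
    mix = lambda a, b: (1.0 - params.m) * a + params.m * b
    nco_none, nco_full = mix(n1, n2), mix(f1, f2)
    nco_side = mix(p1, p2) + mix(s1, s2)
    nco_int = W - nco_none - nco_full - nco_side

    p_cons = (1.0 - lam) + lam * (q * (pad + 1) + (1.0 - q) * (nco_none + nco_full)) / W
    p_one = lam * (q * span + (1.0 - q) * nco_side) / W
    p_two = lam * (1.0 - q) * nco_int / W
    return {
        "consistent": p_cons,
        "one_switch": p_one,
        "two_switch": max(p_two, 0.0),
        "complex": 0.0,
    }


# ---------------------------------------------------------------------------
# Vectorised likelihood over packed reads


class PackedReads:
    """Sufficient statistics of a read set for fast likelihood evaluation.

    Reads are reduced to their window size, inter-marker gaps, and the
    integer exponents describing the observed flip run (and, for
    one-switch patterns, both background hypotheses).  Reads with >= 3
    switches cannot occur under the model and are counted in
    ``n_complex`` but excluded.
    """

    def __init__(self, records: Sequence[MarkerReadRecord], pad: int = DEFAULT_WINDOW_PAD):
        self.pad = pad
        keep: list[MarkerReadRecord] = []
        self.n_complex = 0
        for r in records:
            if r.n < 3:
                raise ValueError(f"read {r.read_id} has {r.n} < 3 markers")
            ns = int(np.count_nonzero(np.diff(r.labels)))
            if ns >= 3:
                self.n_complex += 1
            else:
                keep.append(r)
        self.read_ids = [r.read_id for r in keep]
        R = len(keep)
        self.n_reads = R
        if R == 0:
            raise ValueError("no usable reads (all complex or empty input)")
        self.n_markers = np.array([r.n for r in keep], dtype=np.int64)
        span = np.array([r.positions[-1] - r.positions[0] for r in keep], dtype=np.int64)
        self.span = span
        self.W = span.astype(np.float64) + pad + 1
        gaps = [np.diff(r.positions) for r in keep]
        self.gaps_flat = np.concatenate(gaps) if gaps else np.empty(0, dtype=np.int64)
        self.gap_ptr = np.concatenate(([0], np.cumsum([g.size for g in gaps])[:-1]))
        # gap values repeat heavily across reads: cache unique values so a
        # likelihood evaluation exponentiates ~10^4 numbers, not ~10^6
        self.gap_unique, self.gap_inv = np.unique(self.gaps_flat, return_inverse=True)
        # case codes and flip-run exponents
        case = np.zeros(R, dtype=np.int8)
        # one-switch: suffix run exponents (d0,d1) and prefix run (d0,d1,e0,e1)
        suf = np.zeros((R, 2), dtype=np.int64)
        pre = np.zeros((R, 4), dtype=np.int64)
        sw_gap = np.zeros(R, dtype=np.int64)
        # interior run exponents (d0,d1,e0,e1)
        inter = np.zeros((R, 4), dtype=np.int64)
        for idx, r in enumerate(keep):
            x = r.positions
            runs = _runs(r.labels)
            if len(runs) == 1:
                case[idx] = 0
            elif len(runs) == 2:
                case[idx] = 1
                k = runs[1][0]
                sw_gap[idx] = x[k] - x[k - 1]
                suf[idx] = (x[-1] - x[k], x[-1] - x[k - 1] - 1)
                pre[idx] = (x[k - 1] - x[0], x[k - 1] - x[0] + pad,
                            x[k] - x[0], x[k] - x[0] + pad)
            else:
                case[idx] = 2
                i, j = runs[1]
                d0, d1 = x[j] - x[i], x[j] - x[i - 1] - 1
                e0, e1 = x[j + 1] - x[i], x[j + 1] - x[i - 1] - 1
                inter[idx] = (d0, d1, e0, e1)
        self.case = case
        self.is0 = case == 0
        self.is1 = case == 1
        self.is2 = case == 2
        self.suf = suf
        self.pre = pre
        self.sw_gap = sw_gap.astype(np.float64)
        self.inter = inter

    # -- component masses -------------------------------------------------

    def _component_masses(self, L: float):
        """Masses at mean tract length L: (none, full, side, interior).

        ``none``/``full`` are per-read vectors.  ``side`` is, for
        one-switch reads, the summed NCO mass of the two background
        hypotheses (observed suffix flipped + observed prefix flipped);
        ``interior`` is the exact-run mass for two-switch reads.  Both
        are zero outside their case mask.
        """
        phi = 1.0 - 1.0 / L
        pad = self.pad
        gap_pows = _pow(phi, self.gap_unique)[self.gap_inv]
        gap_sums = (np.add.reduceat(gap_pows, self.gap_ptr)
                    if self.gaps_flat.size else np.zeros(self.n_reads))
        # none mass: W - (n - sum_i phi**c_i) / (1 - phi); for L == 1 the
        # fraction degenerates to n - (number of zero exponents) = n
        sum_pows = _pow(phi, pad + 1) + gap_sums
        if phi > 0:
            none = self.W - (self.n_markers - sum_pows) / (1.0 - phi)
        else:
            none = self.W - (self.n_markers - sum_pows)
        full = _geom_sum(phi, self.span, self.span + pad)
        side = np.zeros(self.n_reads)
        if np.any(self.is1):
            s = self.suf[self.is1]
            p = self.pre[self.is1]
            m_suf = _geom_sum(phi, s[:, 0], s[:, 1])
            m_pre = _geom_sum(phi, p[:, 0], p[:, 1]) - _geom_sum(phi, p[:, 2], p[:, 3])
            side[self.is1] = m_suf + m_pre
        inter = np.zeros(self.n_reads)
        if np.any(self.is2):
            t = self.inter[self.is2]
            inter[self.is2] = _geom_sum(phi, t[:, 0], t[:, 1]) - _geom_sum(phi, t[:, 2], t[:, 3])
        return none, full, side, inter


def loglik(
    packed: PackedReads,
    params: TractModelParams,
    weights: np.ndarray | None = None,
) -> float:
    """Total log-likelihood of packed reads under ``params``.

    ``weights`` (per read) support bootstrap resampling without
    re-packing; default all ones.
    """
    pad = packed.pad
    lam = params.rho * packed.W
    if np.any(lam >= 1.0):
        raise InvalidParameterError("rho * window >= 1 for at least one read")
    q, m = params.q, params.m

    n1, f1, s1, i1 = packed._component_masses(params.L1)
    if m > 0.0:
        n2, f2, s2, i2 = packed._component_masses(params.L2)
    else:
        n2, f2, s2, i2 = n1, f1, s1, i1
    mixv = lambda a, b: (1.0 - m) * a + m * b

    P = np.empty(packed.n_reads)
    # consistent reads
    if np.any(packed.is0):
        sel = packed.is0
        a_none = (1.0 - q) * mixv(n1[sel], n2[sel]) / packed.W[sel]
        a_full = (q * (pad + 1) + (1.0 - q) * mixv(f1[sel], f2[sel])) / packed.W[sel]
        P[sel] = 0.5 * ((1.0 - lam[sel]) + lam[sel] * a_none) + 0.5 * lam[sel] * a_full
    # one-switch reads
    if np.any(packed.is1):
        sel = packed.is1
        a = (q * packed.sw_gap[sel] + (1.0 - q) * mixv(s1[sel], s2[sel])) / packed.W[sel]
        P[sel] = 0.5 * lam[sel] * a
    # two-switch (interior run) reads
    if np.any(packed.is2):
        sel = packed.is2
        P[sel] = 0.5 * lam[sel] * (1.0 - q) * mixv(i1[sel], i2[sel]) / packed.W[sel]
    if np.any(P <= 0.0):
        return -math.inf
    lp = np.log(P)
    if weights is not None:
        lp = lp * weights
    return float(np.sum(lp))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitOptions:
    """Optimisation settings for ``fit_model``."""

    n_starts: int = 20
    seed: int | None = None
    pad: int = DEFAULT_WINDOW_PAD
    maxiter: int = 500
    ftol: float = 1e-13
    gtol: float = 1e-9
    L_max: float = 50_000.0
    L_min: float = 1.0 + 1e-6
    init: TractModelParams | None = None


@dataclass
class FitResult:
    """Maximum-likelihood fit of the tract-length model."""

    model: str
    params: TractModelParams
    loglik: float
    k: int
    aic: float
    n_reads: int
    n_complex_excluded: int
    converged: bool
    n_starts: int
    best_start: int
    seed: int | None = None
    ci: dict[str, tuple[float, float]] | None = None
    n_boot: int | None = None
    n_boot_failed: int | None = None

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2, default=float)


class FitFailureError(RuntimeError):
    pass


def _pack(records, pad) -> PackedReads:
    if isinstance(records, PackedReads):
        return records
    return PackedReads(records, pad=pad)


_LOGIT_CAP = 16.0


def _logit(p: float) -> float:
    p = min(max(p, 1e-7), 1 - 1e-7)
    return math.log(p / (1 - p))


def _expit(u: float) -> float:
    return 1.0 / (1.0 + math.exp(-u))


def _theta_to_params(theta: np.ndarray, model: str) -> TractModelParams:
    if model == "single":
        lrho, uq, u1 = theta
        L = 1.0 + math.exp(u1)
        return TractModelParams(math.exp(lrho), _expit(uq), 0.0, L, L)
    lrho, uq, um, u1, u2 = theta
    L1 = 1.0 + math.exp(u1)
    L2 = L1 + math.exp(u2)
    return TractModelParams(math.exp(lrho), _expit(uq), _expit(um), L1, L2)


def _params_to_theta(p: TractModelParams, model: str) -> np.ndarray:
    if model == "single":
        return np.array([math.log(p.rho), _logit(p.q), math.log(max(p.L1 - 1.0, 1e-6))])
    return np.array([
        math.log(p.rho), _logit(p.q), _logit(p.m),
        math.log(max(p.L1 - 1.0, 1e-6)),
        math.log(max(p.L2 - p.L1, 1e-6)),
    ])


def fit_model(
    records,
    model: str = "mixture",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the single-geometric or two-component mixture model by ML.

    Multi-start quasi-Newton optimisation on transformed parameters
    (log rho, logit q, logit m, log(L1 - 1), log(L2 - L1)); the ordering
    L1 <= L2 is built into the parameterisation.  Reproducible under
    ``options.seed``; ties across starts resolve to the lowest start
    index.
    """
    if model not in ("single", "mixture"):
        raise ValueError(f"unknown model {model!r}")
    opts = options or FitOptions()
    packed = _pack(records, opts.pad)
    rng = np.random.default_rng(opts.seed)

    W_max = float(np.max(packed.W))
    lrho_hi = math.log((1.0 - 1e-9) / W_max)
    lrho_lo = math.log(1e-16)
    uL_lo = math.log(opts.L_min - 1.0)
    uL_hi = math.log(opts.L_max)
    if model == "single":
        bounds = [(lrho_lo, lrho_hi), (-_LOGIT_CAP, _LOGIT_CAP), (uL_lo, uL_hi)]
    else:
        bounds = [(lrho_lo, lrho_hi), (-_LOGIT_CAP, _LOGIT_CAP),
                  (-_LOGIT_CAP, _LOGIT_CAP), (uL_lo, uL_hi), (uL_lo, uL_hi)]

    # moment-flavoured default start: event rate from the switched-read
    # fraction, generic q/m/L guesses
    frac_sw = float(np.mean(packed.case > 0))
    rho0 = max(frac_sw, 1e-6) / W_max * 5.0
    rho0 = min(rho0, (1 - 1e-6) / W_max)
    if opts.init is not None:
        starts = [_params_to_theta(opts.init, model)]
    elif model == "single":
        starts = [np.array([math.log(rho0), _logit(0.3), math.log(50.0)])]
    else:
        starts = [np.array([math.log(rho0), _logit(0.3), _logit(0.05),
                            math.log(50.0), math.log(2000.0)])]
    while len(starts) < opts.n_starts:
        t = starts[0].copy()
        t[0] += rng.uniform(-2.5, 1.0)
        t[0] = min(t[0], lrho_hi - 1e-9)
        t[1] = _logit(rng.uniform(0.02, 0.9))
        if model == "single":
            t[2] = math.log(rng.uniform(2.0, 2000.0))
        else:
            t[2] = _logit(rng.uniform(0.002, 0.4))
            t[3] = math.log(rng.uniform(2.0, 500.0))
            t[4] = math.log(rng.uniform(100.0, 15000.0))
        starts.append(t)

    def nll(theta: np.ndarray) -> float:
        p = _theta_to_params(theta, model)
        ll = loglik(packed, p)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    best = None
    best_ll = -math.inf
    best_idx = -1
    for idx, t0 in enumerate(starts):
        res = minimize(
            nll, t0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        if not np.isfinite(res.fun):
            continue
        if -res.fun > best_ll + 1e-9:
            best_ll = -res.fun
            best = res
            best_idx = idx
    if best is None or not np.isfinite(best_ll):
        raise FitFailureError(f"no start converged to a finite likelihood ({model})")
    params = _theta_to_params(best.x, model)
    k = 3 if model == "single" else 5
    return FitResult(
        model=model,
        params=params,
        loglik=best_ll,
        k=k,
        aic=2 * k - 2 * best_ll,
        n_reads=packed.n_reads,
        n_complex_excluded=packed.n_complex,
        converged=bool(best.success),
        n_starts=len(starts),
        best_start=best_idx,
        seed=opts.seed,
    )


def compare_models(fit_single: FitResult, fit_mixture: FitResult) -> dict[str, float]:
    """AIC comparison of two fits on the same data.

    ``relative_likelihood`` = exp(-dAIC/2) of the worse model relative to
    the better one; ``likelihood_fold_change`` = exp(dlogL).  Both are
    also returned as log10 values, which cannot overflow.
    """
    d_ll = fit_mixture.loglik - fit_single.loglik
    d_aic = fit_mixture.aic - fit_single.aic
    log10_fold = d_ll / math.log(10.0)
    log10_rel = -abs(d_aic) / 2.0 / math.log(10.0)
    return {
        "delta_loglik": d_ll,
        "delta_aic": d_aic,
        "likelihood_fold_change": math.exp(d_ll) if d_ll < 700 else math.inf,
        "log10_likelihood_fold_change": log10_fold,
        "relative_likelihood": 10.0 ** log10_rel if log10_rel > -300 else 0.0,
        "log10_relative_likelihood": log10_rel,
    }


def bootstrap_ci(
    records,
    model: str = "mixture",
    B: int = 200,
    seed: int | None = None,
    options: FitOptions | None = None,
    fit: FitResult | None = None,
) -> FitResult:
    """Nonparametric bootstrap percentile CIs for the fitted parameters.

    Reads are resampled with replacement ``B`` times and the model refit
    from the full-data MLE (resampling is implemented as per-read
    weights, so reads are never re-packed).  Returns a copy of the
    full-data fit with 2.5/97.5 percentile intervals attached.  Refit
    failures are counted; more than 20% failing is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    opts = options or FitOptions()
    packed = _pack(records, opts.pad)
    if packed.n_reads < 2:
        raise ValueError("bootstrap undefined for fewer than 2 reads")
    if fit is None:
        fit = fit_model(packed, model=model, options=opts)
    rng = np.random.default_rng(seed)
    theta_hat = _params_to_theta(fit.params, model)
    names = ["rho", "q", "L1"] if model == "single" else ["rho", "q", "m", "L1", "L2"]
    samples: list[list[float]] = []
    failed = 0
    boot_opts = FitOptions(
        n_starts=1, seed=None, pad=opts.pad, maxiter=opts.maxiter,
        ftol=opts.ftol, gtol=opts.gtol, L_max=opts.L_max, init=fit.params,
    )
    W_max = float(np.max(packed.W))
    lrho_hi = math.log((1.0 - 1e-9) / W_max)
    uL_lo = math.log(boot_opts.L_min - 1.0)
    uL_hi = math.log(boot_opts.L_max)
    if model == "single":
        bounds = [(math.log(1e-16), lrho_hi), (-_LOGIT_CAP, _LOGIT_CAP), (uL_lo, uL_hi)]
    else:
        bounds = [(math.log(1e-16), lrho_hi), (-_LOGIT_CAP, _LOGIT_CAP),
                  (-_LOGIT_CAP, _LOGIT_CAP), (uL_lo, uL_hi), (uL_lo, uL_hi)]
    for _ in range(B):
        w = np.bincount(
            rng.integers(0, packed.n_reads, size=packed.n_reads),
            minlength=packed.n_reads,
        ).astype(np.float64)

        def nll(theta):
            p = _theta_to_params(theta, model)
            ll = loglik(packed, p, weights=w)
            return -ll if np.isfinite(ll) else 1e12

        res = minimize(nll, theta_hat, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": opts.maxiter, "ftol": opts.ftol,
                                "gtol": opts.gtol})
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            failed += 1
            continue
        p = _theta_to_params(res.x, model)
        samples.append([getattr(p, nm) for nm in names])
    if failed > 0.2 * B:
        raise FitFailureError(f"{failed}/{B} bootstrap refits failed")
    arr = np.asarray(samples)
    ci = {nm: (float(np.percentile(arr[:, i], 2.5)), float(np.percentile(arr[:, i], 97.5)))
          for i, nm in enumerate(names)}
    return replace(fit, ci=ci, n_boot=B, n_boot_failed=failed)


# ---------------------------------------------------------------------------
# Detection summaries


@dataclass
class DetectionSummary:
    """How often NCO tracts become visible, and what the visible ones look like."""

    p_detect: float                  # P(tract converts >=1 marker as an interior run)
    long_share: float                # fraction of that mass from the long component
    k_distribution: dict[int, float]  # converted-marker count | detected


def detection_summary(
    params: TractModelParams,
    records,
    pad: int = DEFAULT_WINDOW_PAD,
    max_reads: int | None = None,
) -> DetectionSummary:
    """Window-weighted detection probability of an NCO tract over a read set.

    An NCO is *detected* when its tract converts at least one marker and
    the converted markers form an interior run (a two-switch pattern);
    tracts touching the first or last marker mimic crossovers and are
    not counted.  Events land on a read with probability proportional to
    its window, hence the window weighting.
    """
    if isinstance(records, PackedReads):
        raise TypeError("detection_summary needs raw records (marker positions)")
    recs = list(records)
    if max_reads is not None and len(recs) > max_reads:
        recs = recs[:max_reads]
    tot_W = 0.0
    det_mix = 0.0
    det_long = 0.0
    kdist: dict[int, float] = {}
    for r in recs:
        x = np.asarray(r.positions, dtype=np.int64)
        n = x.size
        tot_W += window_size(x, pad)
        if n < 3:
            continue
        for i in range(1, n - 1):
            for j in range(i, n - 1):
                m1 = _run_mass(x, i, j, params.L1, pad)
                m2 = _run_mass(x, i, j, params.L2, pad) if params.m > 0 else 0.0
                mix = (1.0 - params.m) * m1 + params.m * m2
                det_mix += mix
                det_long += params.m * m2
                k = j - i + 1
                kdist[k] = kdist.get(k, 0.0) + mix
    p_detect = det_mix / tot_W if tot_W else 0.0
    long_share = det_long / det_mix if det_mix > 0 else 0.0
    if det_mix > 0:
        kdist = {k: v / det_mix for k, v in sorted(kdist.items())}
    return DetectionSummary(p_detect=p_detect, long_share=long_share, k_distribution=kdist)
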