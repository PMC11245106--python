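"""Tract-length likelihood: closed forms vs enumeration, fitting, summaries."""

import math

import numpy as np
import pytest

from gamrec import simulate as sim
from gamrec import tractfit as tf


def brute_force_pattern_prob(positions, subset, L, pad, tail=1e-15):
    """Independent oracle: enumerate tract starts against a tabulated pmf.

    The geometric pmf is built term by term and summed numerically
    (reverse cumulative sums -- no geometric-series algebra shared with
    the implementation); for each start the tract must reach the last
    marker of ``subset`` but not the next marker or any earlier one.
    """
    x = np.asarray(positions, dtype=np.int64)
    phi = 1.0 - 1.0 / L
    if phi == 0.0:
        lmax = 1
    else:
        lmax = int(np.ceil(np.log(tail) / np.log(phi))) + 2
    pmf = (1.0 - phi) * phi ** np.arange(lmax)        # lengths 1..lmax
    # ge[k] = P(length >= k) for k = 1..lmax+1, by numerical summation
    ge = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])

    def p_len_ge(k):
        k = np.asarray(k)
        out = np.zeros(k.shape)
        small = k <= lmax
        out[small] = ge[np.maximum(k[small], 1) - 1]
        out[k < 1] = 1.0
        return out

    W = int(x[-1] - x[0]) + pad + 1
    subset = sorted(set(subset))
    if not subset:
        # complement: converting nothing = 1 - sum over all contiguous runs
        return 1.0 - sum(
            brute_force_pattern_prob(positions, set(range(i, j + 1)), L, pad, tail)
            for i in range(x.size) for j in range(i, x.size))
    i, j = subset[0], subset[-1]
    if subset != list(range(i, j + 1)):
        return 0.0
    s_lo = int(x[i - 1]) + 1 if i > 0 else int(x[0]) - pad
    s = np.arange(s_lo, int(x[i]) + 1)
    reach_j = p_len_ge(x[j] - s + 1)                  # tract covers x_j
    if j < x.size - 1:
        reach_next = p_len_ge(x[j + 1] - s + 1)       # ...but not x_{j+1}
    else:
        reach_next = np.zeros_like(reach_j)
    return float(np.sum(reach_j - reach_next)) / W


class TestPatternProb:
    def test_degenerate_length_one(self):
        x = [100, 200, 300]
        # only start 200 with length 1 converts exactly marker 1
        W = 200 + 500 + 1
        assert tf.nco_pattern_prob(x, {1}, L=1.0, pad=500) == pytest.approx(1 / W)
        # a 1-bp tract cannot span two markers
        assert tf.nco_pattern_prob(x, {0, 1}, L=1.0, pad=500) == 0.0

    def test_noncontiguous_subset_impossible(self):
        assert tf.nco_pattern_prob([100, 200, 300], {0, 2}, L=50.0, pad=500) == 0.0

    @pytest.mark.parametrize("L", [1.0, 2.0, 34.6, 7214.1])
    def test_matches_enumeration(self, L):
        x = [100, 200, 300]
        pad = 500
        subsets = [set(), {0}, {1}, {2}, {0, 1}, {1, 2}, {0, 1, 2}]
        for subset in subsets:
            closed = tf.nco_pattern_prob(x, subset, L, pad=pad)
            brute = brute_force_pattern_prob(x, subset, L, pad)
            assert closed == pytest.approx(brute, abs=1e-10), (L, subset)

    def test_invalid_length(self):
        with pytest.raises(tf.InvalidParameterError):
            tf.nco_pattern_prob([10, 20], {0}, L=0.5)


class TestReadPatternLoglik:
    PARAMS = tf.TractModelParams(rho=2e-6, q=0.3, m=0.1, L1=30.0, L2=5000.0)

    @pytest.mark.parametrize("n_markers", [3, 5, 8, 12])
    def test_pattern_probabilities_sum_to_one(self, n_markers, rng):
        x = np.sort(rng.choice(30_000, size=n_markers, replace=False))
        total = 0.0
        for pat in range(2 ** n_markers):
            labels = 1 + ((pat >> np.arange(n_markers)) & 1)
            lp = tf.read_pattern_logprob(x, labels, self.PARAMS, pad=100_000)
            if lp > -math.inf:
                total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_rho_zero(self):
        x = [100, 2000, 9000]
        params = tf.TractModelParams(rho=0.0, q=0.5, m=0.0, L1=30, L2=30)
        # each consistent labelling carries one background hypothesis (1/2);
        # the consistent class as a whole is certain, switches impossible
        assert tf.read_pattern_logprob(x, [1, 1, 1], params) == pytest.approx(
            math.log(0.5))
        assert tf.pattern_class_probs(x, params)["consistent"] == pytest.approx(1.0)
        assert tf.read_pattern_logprob(x, [1, 2, 1], params) == -math.inf

    def test_mixture_degeneracy(self):
        x = [100, 2000, 9000]
        labels = [1, 2, 2]
        a = tf.TractModelParams(rho=1e-6, q=0.2, m=0.0, L1=40, L2=40)
        b = tf.TractModelParams(rho=1e-6, q=0.2, m=1.0, L1=40, L2=40)
        assert (tf.read_pattern_logprob(x, labels, a)
                == pytest.approx(tf.read_pattern_logprob(x, labels, b)))

    def test_rho_window_bound(self):
        params = tf.TractModelParams(rho=1e-2, q=0.2, m=0.0, L1=40, L2=40)
        with pytest.raises(tf.InvalidParameterError):
            tf.read_pattern_logprob([100, 200, 300], [1, 1, 1], params)

    def test_packed_equals_scalar(self, rng):
        recs = []
        for i in range(200):
            n = int(rng.integers(3, 12))
            x = np.sort(rng.choice(25_000, size=n, replace=False))
            if rng.random() < 0.7:
                labels = np.full(n, 1 + int(rng.integers(0, 2)))
            else:
                labels = 1 + (rng.random(n) < 0.5).astype(int)
            recs.append(tf.MarkerReadRecord(f"r{i}", x, labels))
        params = tf.TractModelParams(rho=1e-6, q=0.2, m=0.05, L1=40, L2=4000)
        packed = tf.PackedReads(recs, pad=200_000)
        scalar = sum(
            tf.read_pattern_logprob(r.positions, r.labels, params, pad=200_000)
            for r in recs
            if int(np.count_nonzero(np.diff(r.labels))) < 3
        )
        assert tf.loglik(packed, params) == pytest.approx(scalar, rel=1e-10)

    def test_mixture_at_m_zero_equals_single(self, rng):
        recs = [
            tf.MarkerReadRecord("a", [100, 5000, 9000], [1, 1, 1]),
            tf.MarkerReadRecord("b", [50, 1000, 1500, 8000], [1, 2, 2, 1]),
            tf.MarkerReadRecord("c", [10, 700, 7000], [2, 2, 1]),
        ]
        packed = tf.PackedReads(recs)
        mix = tf.TractModelParams(rho=1e-6, q=0.3, m=0.0, L1=50, L2=9000)
        single = tf.TractModelParams.single(rho=1e-6, q=0.3, L=50)
        assert tf.loglik(packed, mix) == tf.loglik(packed, single)


class TestClassProbs:
    def test_class_probs_sum_and_match_enumeration(self, rng):
        params = tf.TractModelParams(rho=2e-6, q=0.25, m=0.08, L1=25, L2=3000)
        x = np.sort(rng.choice(20_000, size=6, replace=False))
        probs = tf.pattern_class_probs(x, params, pad=50_000)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        # enumerate all label vectors and bin by switch count
        by_class = {"consistent": 0.0, "one_switch": 0.0, "two_switch": 0.0}
        for pat in range(2 ** 6):
            labels = 1 + ((pat >> np.arange(6)) & 1)
            lp = tf.read_pattern_logprob(x, labels, params, pad=50_000)
            if lp == -math.inf:
                continue
            ns = int(np.count_nonzero(np.diff(labels)))
            key = {0: "consistent", 1: "one_switch", 2: "two_switch"}[ns]
            by_class[key] += math.exp(lp)
        for key, val in by_class.items():
            assert probs[key] == pytest.approx(val, abs=1e-12), key


class TestFitting:
    def test_single_model_recovery(self):
        """Single-geometric data at (q=0.15, L=30), 10^5 reads: the true
        mean tract length and CO fraction land inside the fit's own
        bootstrap CIs."""
        cfg = sim.SimulationConfig.tract_study(
            n_reads=100_000, seed=77, co_fraction_q=0.15,
            mixture_weight_m=0.0, tract_mean_L1=30.0, tract_mean_L2=30.0)
        rng = np.random.default_rng(77)
        reads = sim.simulate_reads(sim.build_marker_map(cfg, rng), cfg, rng)
        recs = sim.records_from_reads(reads)
        opts = tf.FitOptions(n_starts=5, seed=3)
        fit = tf.fit_model(recs, "single", opts)
        fit = tf.bootstrap_ci(recs, "single", B=40, seed=9, options=opts, fit=fit)
        lo, hi = fit.ci["L1"]
        assert lo <= 30.0 <= hi
        lo_q, hi_q = fit.ci["q"]
        assert lo_q <= 0.15 <= hi_q

    def test_refit_deterministic(self):
        cfg = sim.SimulationConfig.tract_study(n_reads=3_000, seed=21)
        rng = np.random.default_rng(21)
        reads = sim.simulate_reads(sim.build_marker_map(cfg, rng), cfg, rng)
        recs = sim.records_from_reads(reads)
        opts = tf.FitOptions(n_starts=3, seed=4)
        a = tf.fit_model(recs, "single", opts)
        b = tf.fit_model(recs, "single", opts)
        assert a.loglik == b.loglik
        assert a.params == b.params

    def test_aic_definition(self):
        r = tf.FitResult(model="single", params=tf.TractModelParams.single(1e-7, 0.1, 30),
                         loglik=-100.0, k=3, aic=2 * 3 - 2 * (-100.0), n_reads=10,
                         n_complex_excluded=0, converged=True, n_starts=1, best_start=0)
        assert r.aic == 206.0


class TestCompareModels:
    def _fit(self, loglik, k, model):
        p = tf.TractModelParams(1e-7, 0.1, 0.0, 30, 30)
        return tf.FitResult(model=model, params=p, loglik=loglik, k=k,
                            aic=2 * k - 2 * loglik, n_reads=1, n_complex_excluded=0,
                            converged=True, n_starts=1, best_start=0)

    def test_published_loglik_pair(self):
        """The reported single/mixture log-likelihoods imply a > 1e59-fold
        improvement and a relative likelihood of ~1.3-1.4e-59."""
        single = self._fit(-26863.9, 3, "single")
        mixture = self._fit(-26726.4, 5, "mixture")
        cmpres = tf.compare_models(single, mixture)
        assert cmpres["likelihood_fold_change"] > 1e59
        assert cmpres["delta_loglik"] == pytest.approx(137.5)
        assert cmpres["relative_likelihood"] == pytest.approx(
            math.exp(-(single.aic - mixture.aic) / 2), rel=1e-9)
        assert 1.0e-59 < cmpres["relative_likelihood"] < 2.0e-59

    def test_identical_fits(self):
        a = self._fit(-500.0, 3, "single")
        b = self._fit(-500.0, 5, "mixture")
        cmpres = tf.compare_models(a, b)
        assert cmpres["likelihood_fold_change"] == pytest.approx(1.0)
        # equal logL: relative likelihood = exp(-delta_k)
        assert cmpres["relative_likelihood"] == pytest.approx(math.exp(-2.0))

    def test_arbitrary_pair_matches_arithmetic(self):
        a = self._fit(-120.4, 3, "single")
        b = self._fit(-118.9, 5, "mixture")
        cmpres = tf.compare_models(a, b)
        assert cmpres["delta_aic"] == pytest.approx(b.aic - a.aic)
        assert cmpres["likelihood_fold_change"] == pytest.approx(math.exp(1.5))


class TestBootstrap:
    def _records(self):
        cfg = sim.SimulationConfig.tract_study(n_reads=2_000, seed=13)
        rng = np.random.default_rng(13)
        reads = sim.simulate_reads(sim.build_marker_map(cfg, rng), cfg, rng)
        return sim.records_from_reads(reads)

    def test_deterministic_under_seed(self):
        recs = self._records()
        opts = tf.FitOptions(n_starts=2, seed=1)
        fit = tf.fit_model(recs, "single", opts)
        a = tf.bootstrap_ci(recs, "single", B=2, seed=7, options=opts, fit=fit)
        b = tf.bootstrap_ci(recs, "single", B=2, seed=7, options=opts, fit=fit)
        assert a.ci == b.ci

    def test_degenerate_input(self):
        rec = [tf.MarkerReadRecord("a", [100, 5000, 9000], [1, 1, 1])]
        with pytest.raises((ValueError, tf.FitFailureError)):
            tf.bootstrap_ci(rec, "single", B=2, seed=0)

    def test_b_too_small(self):
        with pytest.raises(ValueError):
            tf.bootstrap_ci(self._records(), "single", B=1, seed=0)


class TestDetectionSummary:
    def test_toy_read_matches_enumeration(self):
        """3-marker read: detection mass equals the middle-marker-only
        pattern probability; k-distribution is all k=1."""
        params = tf.TractModelParams(rho=1e-6, q=0.3, m=0.1, L1=20, L2=800)
        rec = tf.MarkerReadRecord("a", [1000, 1600, 2500], [1, 1, 1])
        pad = 10_000
        ds = tf.detection_summary(params, [rec], pad=pad)
        p_mid_1 = tf.nco_pattern_prob(rec.positions, {1}, params.L1, pad)
        p_mid_2 = tf.nco_pattern_prob(rec.positions, {1}, params.L2, pad)
        expect = (1 - params.m) * p_mid_1 + params.m * p_mid_2
        assert ds.p_detect == pytest.approx(expect, rel=1e-12)
        assert ds.long_share == pytest.approx(params.m * p_mid_2 / expect, rel=1e-12)
        assert ds.k_distribution == {1: pytest.approx(1.0)}

    def test_no_long_component_no_long_share(self):
        params = tf.TractModelParams(rho=1e-6, q=0.3, m=0.0, L1=20, L2=800)
        rec = tf.MarkerReadRecord("a", [1000, 1600, 2500], [1, 1, 1])
        assert tf.detection_summary(params, [rec]).long_share == 0.0

    def test_long_tracts_rarely_interior(self):
        """Near-infinite tracts overrun the read: interior (two-switch)
        detection mass stays small relative to the tract frequency."""
        rec = tf.MarkerReadRecord("a", [1000, 1600, 2500], [1, 1, 1])
        long_params = tf.TractModelParams(rho=1e-8, q=0.0, m=1.0, L1=5e5, L2=5e5)
        short_params = tf.TractModelParams(rho=1e-8, q=0.0, m=0.0, L1=300, L2=300)
        d_long = tf.detection_summary(long_params, [rec], pad=10_000)
        d_short = tf.detection_summary(short_params, [rec], pad=10_000)
        assert d_long.p_detect < d_short.p_detect


class TestParamsValidation:
    def test_ordering_enforced_by_swap(self):
        p = tf.TractModelParams(rho=1e-7, q=0.1, m=0.9, L1=500, L2=20)
        assert (p.L1, p.L2) == (20, 500)
        assert p.m == pytest.approx(0.1)

    def test_invalid_values(self):
        with pytest.raises(tf.InvalidParameterError):
            tf.TractModelParams(rho=-1e-7, q=0.1, m=0.1, L1=20, L2=30)
        with pytest.raises(tf.InvalidParameterError):
            tf.TractModelParams(rho=1e-7, q=1.5, m=0.1, L1=20, L2=30)
        with pytest.raises(tf.InvalidParameterError):
            tf.TractModelParams(rho=1e-7, q=0.5, m=0.1, L1=0.2, L2=30)
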