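"""Evaluation metrics against independent loop-based oracles and edge cases."""

import math

import numpy as np
import pytest

from iccode import metrics as mt
from iccode.errors import MetricError
from iccode.model_core import CountDistribution
from iccode.neural_preproc import MUAResponse
from iccode.stimuli import Annotation


# ---------------------------------------------------------------------------
# naive loop-based oracles (kept deliberately simple and independent)


def oracle_rmse(r, rhat):
    total = 0.0
    m, t = len(r), len(r[0])
    for i in range(m):
        for j in range(t):
            total += (r[i][j] - rhat[i][j]) ** 2
    return math.sqrt(total / (m * t))


def oracle_corr(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def oracle_correlation_explained(r1, r2, h1, h2):
    f = lambda x: [v for row in x for v in row]  # noqa: E731
    return 50.0 * (oracle_corr(f(r1), f(h1)) + oracle_corr(f(r2), f(h2))) / oracle_corr(
        f(r1), f(r2)
    )


def oracle_variance_explained(r1, r2, e1, e2):
    def var(v):
        m = sum(v) / len(v)
        return sum((x - m) ** 2 for x in v) / len(v)

    f = lambda x: [v for row in x for v in row]  # noqa: E731
    noise = 0.5 * var([a - b for a, b in zip(f(r1), f(r2))])
    mt_ = len(f(r1))
    err = (sum((a - b) ** 2 for a, b in zip(f(r1), f(e1))) / (2 * mt_)
           + sum((a - b) ** 2 for a, b in zip(f(r2), f(e2))) / (2 * mt_))
    denom = 0.5 * (var(f(r1)) + var(f(r2))) - noise
    return 100.0 * (1.0 - (err - noise) / denom)


def oracle_poisson_logpmf(lam, k):
    return k * math.log(lam) - lam - math.lgamma(k + 1)


def oracle_fano(trials, unit):
    n_tr, t = len(trials), len(trials[0][0])
    vals = []
    for j in range(t):
        col = [trials[i][unit][j] for i in range(n_tr)]
        m = sum(col) / n_tr
        if m == 0:
            continue
        v = sum((x - m) ** 2 for x in col) / (n_tr - 1)
        vals.append(v / m)
    return sum(vals) / len(vals)


def oracle_nonstationarity(succ, sep):
    def cov(a, b):
        a = [v for row in a for v in row]
        b = [v for row in b for v in row]
        ma = sum(a) / len(a)
        mb = sum(b) / len(b)
        return sum((x - ma) * (y - mb) for x, y in zip(a, b)) / (len(a) - 1)

    s1 = sum(cov(*p) for p in succ) / len(succ)
    s2 = sum(cov(*p) for p in sep) / len(sep)
    return abs(s1 - s2)


@pytest.fixture
def random_pair(rng):
    r1 = rng.integers(0, 5, (5, 20)).astype(float)
    r2 = np.clip(r1 + rng.integers(-1, 2, (5, 20)), 0, 4).astype(float)
    h1 = np.clip(r1 + rng.integers(-1, 2, (5, 20)), 0, 4).astype(float)
    h2 = np.clip(r2 + rng.integers(-1, 2, (5, 20)), 0, 4).astype(float)
    lam1 = rng.uniform(0.2, 2.0, (5, 20))
    lam2 = rng.uniform(0.2, 2.0, (5, 20))
    return mt.TrialPair(r1, r2, h1, h2,
                        CountDistribution("poisson", lam=lam1),
                        CountDistribution("poisson", lam=lam2))


class TestOracleEquivalence:
    def test_rmse_matches_loop_oracle(self, random_pair):
        p = random_pair
        assert mt.rmse_metric(p.r1, p.rhat1) == pytest.approx(
            oracle_rmse(p.r1.tolist(), p.rhat1.tolist()), abs=1e-10)

    def test_loglik_matches_loop_oracle(self, random_pair):
        p = random_pair
        lam = p.dist1.lam
        expect = np.mean([
            oracle_poisson_logpmf(lam[i][j], p.r1[i][j])
            for i in range(5) for j in range(20)
        ])
        assert mt.loglik_metric(p.dist1, p.r1) == pytest.approx(expect, abs=1e-10)

    def test_correlation_explained_matches_loop_oracle(self, random_pair):
        p = random_pair
        expect = oracle_correlation_explained(
            p.r1.tolist(), p.r2.tolist(), p.rhat1.tolist(), p.rhat2.tolist())
        assert mt.correlation_explained(p) == pytest.approx(expect, abs=1e-10)

    def test_variance_explained_matches_loop_oracle(self, random_pair):
        p = random_pair
        expect = oracle_variance_explained(
            p.r1.tolist(), p.r2.tolist(), p.dist1.lam.tolist(), p.dist2.lam.tolist())
        assert mt.variance_explained(p) == pytest.approx(expect, abs=1e-10)

    def test_fano_matches_loop_oracle(self, rng):
        trials = rng.integers(0, 5, (6, 5, 20)).astype(float)
        got = mt.fano_factor(trials)
        for u in range(5):
            assert got[u] == pytest.approx(oracle_fano(trials.tolist(), u), abs=1e-10)

    def test_nonstationarity_matches_loop_oracle(self, rng):
        pairs = [(rng.integers(0, 5, (4, 15)).astype(float),
                  rng.integers(0, 5, (4, 15)).astype(float)) for _ in range(4)]
        got = mt.nonstationarity_index(pairs[:2], pairs[2:])
        expect = oracle_nonstationarity([(a.tolist(), b.tolist()) for a, b in pairs[:2]],
                                        [(a.tolist(), b.tolist()) for a, b in pairs[2:]])
        assert got == pytest.approx(expect, abs=1e-10)


class TestPerfectPrediction:
    def test_both_metrics_exactly_100_percent(self, rng):
        r = rng.integers(0, 5, (5, 40)).astype(float)
        d = CountDistribution("poisson", lam=np.maximum(r, 1e-12))
        pair = mt.TrialPair(r, r, r, r, d, d)
        assert mt.correlation_explained(pair) == 100.0
        assert mt.variance_explained(pair) == 100.0


class TestCorrelationExplained:
    def test_swapped_trials_give_100(self, rng):
        r1 = rng.integers(0, 5, (4, 50)).astype(float)
        r2 = np.clip(r1 + rng.integers(-1, 2, r1.shape), 0, 4).astype(float)
        pair = mt.TrialPair(r1, r2, rhat1=r2, rhat2=r1)
        assert mt.correlation_explained(pair) == pytest.approx(100.0)

    def test_uncorrelated_predictions_near_zero(self, rng):
        base = rng.normal(1.5, 0.5, (10, 10000))
        r1 = np.clip(np.round(base + rng.normal(0, 0.3, base.shape)), 0, 4)
        r2 = np.clip(np.round(base + rng.normal(0, 0.3, base.shape)), 0, 4)
        noise = np.clip(np.round(rng.normal(1.5, 0.5, base.shape)), 0, 4)
        pair = mt.TrialPair(r1, r2, rhat1=noise, rhat2=noise)
        assert abs(mt.correlation_explained(pair)) < 5.0

    def test_above_100_possible(self, rng):
        base = rng.normal(2.0, 0.7, (5, 2000))
        r1 = base + rng.normal(0, 0.8, base.shape)
        r2 = base + rng.normal(0, 0.8, base.shape)
        pair = mt.TrialPair(r1, r2, rhat1=base, rhat2=base)  # noiseless prediction
        assert mt.correlation_explained(pair) > 100.0

    def test_nonpositive_denominator_flagged(self, rng):
        r1 = rng.normal(0, 1, (3, 200))
        r2 = -r1
        pair = mt.TrialPair(r1, r2, rhat1=r1, rhat2=r2)
        with pytest.raises(MetricError):
            mt.correlation_explained(pair)


class TestVarianceExplained:
    def test_grand_mean_prediction_is_zero_percent(self, rng):
        r = rng.integers(0, 5, (4, 100)).astype(float)
        mean_pred = np.full_like(r, r.mean())
        d = CountDistribution("poisson", lam=np.maximum(mean_pred, 1e-12))
        pair = mt.TrialPair(r, r, r, r, d, d)
        assert mt.variance_explained(pair) == pytest.approx(0.0, abs=1e-9)

    def test_negative_when_error_exceeds_explainable_variance(self, rng):
        base = rng.normal(2.0, 0.5, (5, 500))
        r1 = np.clip(np.round(base), 0, 4)
        r2 = np.clip(np.round(base + rng.normal(0, 0.2, base.shape)), 0, 4)
        bad = np.abs(4.0 - base)  # badly wrong expectation
        d = CountDistribution("poisson", lam=bad)
        pair = mt.TrialPair(r1, r2, r1, r2, d, d)
        assert mt.variance_explained(pair) < 0.0


class TestCoherence:
    def test_identical_trials_coherence_one(self, rng):
        r = rng.normal(1.0, 0.5, (4, 400))
        f, coh = mt.coherence_metric(r, r, n_bins=51)
        assert np.allclose(coh[np.isfinite(coh)], 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        r1 = rng.normal(1.0, 0.5, (3, 400))
        r2 = rng.normal(1.0, 0.5, (3, 400))
        _, c1 = mt.coherence_metric(r1, r2, n_bins=51)
        _, c2 = mt.coherence_metric(3.7 * r1, 0.2 * r2, n_bins=51)
        assert np.allclose(c1, c2, atol=1e-9)

    def test_independent_noise_near_segment_floor(self, rng):
        r1 = rng.normal(0, 1, (20, 4000))
        r2 = rng.normal(0, 1, (20, 4000))
        _, coh = mt.coherence_metric(r1, r2, n_bins=101)
        n_segments = 4000 // 200
        assert np.nanmean(coh) < 3.0 / n_segments


class TestFanoFactor:
    def test_identical_trials_zero(self):
        r = np.tile(np.arange(1, 5, dtype=float), (3, 2, 1))
        assert np.allclose(mt.fano_factor(r), 0.0)

    def test_half_half_counts_give_one(self):
        trials = np.array([0.0, 2.0, 0.0, 2.0]).reshape(4, 1, 1)
        got = mt.fano_factor(trials)
        # across-trial sample variance 4/3, mean 1 -> unbiased ratio 4/3;
        # with the population variance it would be exactly 1
        assert got[0] == pytest.approx(4.0 / 3.0)

    def test_poisson_trials_near_one(self, rng):
        trials = rng.poisson(1.3, (128, 6, 200)).astype(float)
        assert np.all(np.abs(mt.fano_factor(trials) - 1.0) < 0.1)


class TestSynchrony:
    def test_constant_response_zero(self):
        trials = np.ones((2, 3, 763))
        s = mt.synchrony_mtf(trials, mod_freq=8.0)
        assert np.allclose(s, 0.0)

    def test_full_modulation_gives_quarter(self):
        t = np.arange(763)
        f = 8.0 / 763.0  # integer number of cycles over the window
        r = 1.0 + np.cos(2 * np.pi * f * t)
        s = mt.synchrony_mtf(np.stack([r[None], r[None]]), mod_freq=f, bin_rate=1.0)
        assert s[0] == pytest.approx(0.25, abs=1e-12)

    def test_invariant_to_rate_scaling(self, rng):
        r = rng.poisson(2.0, (4, 2, 763)).astype(float)
        s1 = mt.synchrony_mtf(r, mod_freq=16.0)
        s2 = mt.synchrony_mtf(5.0 * r, mod_freq=16.0)
        assert np.allclose(s1, s2)


class TestTuningSummary:
    def _response(self, counts, bin_rate=762.9395):
        return MUAResponse(counts, bin_rate=bin_rate)

    def test_uniform_rate_gives_flat_grid(self):
        resp = self._response(np.full((3, 1000), 2))
        anns = [Annotation(i * 0.2, 0.05, "tone", {"frequency": 500.0 * (i + 1),
                                                   "level": 60.0}) for i in range(4)]
        table = mt.tuning_summary(resp, anns, by=["frequency", "level"])
        assert np.allclose(table["mean_count"], 2.0)

    def test_window_start_excludes_first_six_bins(self):
        sl = mt.window_to_bins(0.0079, 0.05)
        assert sl.start == 6

    def test_event_beyond_recording_rejected(self):
        resp = self._response(np.zeros((1, 10)))
        with pytest.raises(MetricError):
            mt.windowed_unit_means(resp, [Annotation(1.0, 0.05, "tone", {})], (0.0, 0.05))


class TestNonstationarityIndex:
    def test_invariant_to_unit_ordering(self, rng):
        pairs = [(rng.integers(0, 5, (6, 30)).astype(float),
                  rng.integers(0, 5, (6, 30)).astype(float)) for _ in range(4)]
        v1 = mt.nonstationarity_index(pairs[:2], pairs[2:])
        perm = rng.permutation(6)
        shuffled = [(a[perm], b[perm]) for a, b in pairs]
        v2 = mt.nonstationarity_index(shuffled[:2], shuffled[2:])
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestBottleneckPCA:
    def test_rank_one_bottleneck_first_component_everything(self, rng):
        rb = np.outer(rng.normal(0, 1, 8), rng.normal(0, 1, 200))
        comps, frac = mt.bottleneck_pca(rb, np.zeros((8, 20)))
        assert frac[0] == pytest.approx(1.0)

    def test_silence_input_normalizes_to_zero(self, rng):
        sil = rng.normal(0, 1, (8, 50))
        rb = np.tile(sil.mean(axis=1, keepdims=True), (1, 100))
        comps, frac = mt.bottleneck_pca(rb, sil)
        assert np.allclose(comps, 0.0)

    def test_variance_fractions_sum_to_one(self, rng):
        rb = rng.normal(0, 1, (6, 300))
        _, frac = mt.bottleneck_pca(rb, np.zeros((6, 10)))
        assert frac.sum() == pytest.approx(1.0)

    def test_fewer_bins_than_channels_rejected(self):
        with pytest.raises(MetricError):
            mt.bottleneck_pca(np.zeros((10, 5)), np.zeros((10, 5)))


class TestBootstrap:
    def test_ci_contains_median_and_shrinks_with_units(self, rng):
        small = rng.normal(50.0, 10.0, 25)
        large = rng.normal(50.0, 10.0, 400)
        rep_s = mt.bootstrap_report(small, seed=1)
        rep_l = mt.bootstrap_report(large, seed=1)
        assert rep_s.ci_low <= rep_s.median <= rep_s.ci_high
        width_s = rep_s.ci_high - rep_s.ci_low
        width_l = rep_l.ci_high - rep_l.ci_low
        assert width_l < width_s / 2.0  # ~1/sqrt(M) scaling
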