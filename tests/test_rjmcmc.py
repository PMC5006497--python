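"""RJMCMC engine: chain statistics, moves, and a tiny-posterior oracle."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp

from plumevol.ctmc import RateConfiguration, build_rate_matrix, log_likelihood
from plumevol.phylo import Phylogeny
from plumevol.rjmcmc import (
    ChainConfig,
    GammaHyper,
    MOVE_REVIVE,
    ModelSample,
    check_convergence,
    harmonic_mean_logml,
    ljung_box,
    move_probabilities,
    propose_move,
    run_chain,
    run_chains,
    thin,
)
from plumevol.states import ABSENCE, SCALES, STATE_ORDER
from plumevol.traits import TraitColumn


class TestHarmonicMean:
    def test_constant_series_is_exact(self):
        assert harmonic_mean_logml([-10.0] * 7) == pytest.approx(-10.0)

    def test_two_point_series(self):
        expected = -(logsumexp([1.0, 3.0]) - math.log(2))
        assert harmonic_mean_logml([-1.0, -3.0]) == pytest.approx(expected)
        # direct arithmetic: -(log((e^1 + e^3)/2)) = -2.43378...
        assert expected == pytest.approx(-2.433781, abs=1e-6)

    def test_duplicate_keeps_value_between_bounds(self):
        base = harmonic_mean_logml([-1.0, -3.0])
        dup = harmonic_mean_logml([-1.0, -3.0, -3.0])
        assert -3.0 <= dup <= -1.0
        assert dup <= base  # extra weight on the smaller likelihood

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_logml([])


class TestConvergence:
    def test_within_one_lnhm(self):
        ok, diff = check_convergence([-100.2, -100.5, -100.9, -101.1])
        assert ok and diff == pytest.approx(0.9)

    def test_beyond_one_lnhm(self):
        ok, diff = check_convergence([-100.0, -102.0])
        assert not ok and diff == pytest.approx(2.0)

    def test_identical_runs(self):
        ok, diff = check_convergence([-5.0, -5.0, -5.0])
        assert ok and diff == 0.0

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            check_convergence([-5.0])


class TestLjungBox:
    def test_zero_lag1_autocorrelation_gives_p_one(self):
        # period-4 pattern whose lag-1 products are all exactly 0
        x = np.array([1.0, 0.0, -1.0, 0.0] * 50)
        q, p = ljung_box(x, lag=1)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.diagnostic")
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        q, p = ljung_box(x, lag=3)
        table = sm.acorr_ljungbox(x, lags=[3])
        assert q == pytest.approx(float(table["lb_stat"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(table["lb_pvalue"].iloc[0]), rel=1e-9)

    def test_ar1_series_rejected(self):
        rng = np.random.default_rng(1)
        rejected = 0
        for _ in range(50):
            e = rng.normal(size=1000)
            x = np.empty(1000)
            x[0] = e[0]
            for i in range(1, 1000):
                x[i] = 0.9 * x[i - 1] + e[i]
            if ljung_box(x, lag=1)[1] < 0.05:
                rejected += 1
        assert rejected == 50

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            ljung_box([2.0] * 10, lag=1)

    def test_bad_lag(self):
        with pytest.raises(ValueError):
            ljung_box([1.0, 2.0], lag=2)


class TestThin:
    def test_identity(self):
        assert thin([1, 2, 3], 1) == [1, 2, 3]

    def test_every_tenth_preserves_order(self):
        out = thin(list(range(100)), 10)
        assert out == list(range(0, 100, 10))

    def test_composition(self):
        xs = list(range(64))
        assert thin(thin(xs, 2), 2) == thin(xs, 4)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            thin([1], 0)


class TestMoves:
    def test_all_zero_only_revive_feasible(self):
        cfg = RateConfiguration.all_zero((ABSENCE, SCALES))
        probs = move_probabilities(cfg)
        assert probs == {MOVE_REVIVE: 1.0}

    def test_proposals_always_valid_configurations(self):
        rng = np.random.default_rng(12)
        hyper = GammaHyper(mean_bounds=(0.5, 1.0))
        cfg = RateConfiguration.single_class(STATE_ORDER, 0.5)
        for _ in range(500):
            prop, log_hr, _move = propose_move(cfg, rng, hyper)
            assert np.isfinite(log_hr)
            if prop is not None:
                prop.copy()  # re-runs invariant validation
                cfg = prop

    def test_rate_walk_hastings_ratio_is_log_rate_ratio(self):
        rng = np.random.default_rng(3)
        hyper = GammaHyper(mean_bounds=(0.5, 1.0))
        cfg = RateConfiguration.single_class((ABSENCE, SCALES), 1.0)
        seen = 0
        for _ in range(200):
            prop, log_hr, move = propose_move(cfg, rng, hyper)
            if move == "rate_walk" and prop is not None:
                expected = math.log(prop.class_rates[0] / cfg.class_rates[0])
                assert log_hr == pytest.approx(expected, abs=1e-12)
                seen += 1
        assert seen > 10


def _tiny_posterior_oracle(tree, col, hyper):
    """Quadrature posterior over the five 2-state configurations."""
    states = (ABSENCE, SCALES)

    def like(q01, q10):
        rates = {}
        if q01 > 0:
            rates[(ABSENCE, SCALES)] = q01
        if q10 > 0:
            rates[(SCALES, ABSENCE)] = q10
        cfg = RateConfiguration.from_rates(states, rates)
        return math.exp(log_likelihood(tree, col, build_rate_matrix(cfg, states),
                                       states=states))

    def g(r):
        return math.exp(hyper.log_pdf(r))

    z_zz = like(0, 0)
    z_z0 = quad(lambda r: g(r) * like(0, r), 0, 20, limit=200)[0]
    z_0z = quad(lambda r: g(r) * like(r, 0), 0, 20, limit=200)[0]
    z_00 = quad(lambda r: g(r) * like(r, r), 0, 20, limit=200)[0]
    z_01 = quad(
        lambda r1: g(r1) * quad(
            lambda r2: g(r2) * like(r1, r2), 0, 20, limit=60
        )[0],
        0, 20, limit=60,
    )[0]
    masses = {"Z,Z": z_zz, "Z,0": z_z0, "0,Z": z_0z, "0,0": z_00, "0,1": z_01}
    total = sum(masses.values())
    return {k: v / total for k, v in masses.items()}


class TestChain:
    def test_fixed_seed_reproducible(self, balanced_tree):
        col = TraitColumn(
            {"A": {ABSENCE}, "B": {ABSENCE}, "C": {SCALES}, "D": {SCALES}}
        )
        cfg = ChainConfig(n_generations=2000, burn_in=200, sample_interval=20,
                          n_chains=1, seed=5, hyper_interval=(0.5, 0.25))
        r1 = run_chain(balanced_tree, col, cfg, states=(ABSENCE, SCALES))
        r2 = run_chain(balanced_tree, col, cfg, states=(ABSENCE, SCALES))
        assert [s.signature for s in r1.samples] == [s.signature for s in r2.samples]
        assert [s.log_likelihood for s in r1.samples] == [
            s.log_likelihood for s in r2.samples
        ]

    def test_uninformative_data_likelihood_constant(self, balanced_tree):
        col = TraitColumn({t: {ABSENCE, SCALES} for t in "ABCD"})
        cfg = ChainConfig(n_generations=1500, burn_in=100, sample_interval=10,
                          n_chains=1, seed=2, hyper_interval=(1.0, 0.5))
        res = run_chain(balanced_tree, col, cfg, states=(ABSENCE, SCALES))
        assert all(s.log_likelihood == pytest.approx(0.0) for s in res.samples)

    def test_matches_tiny_posterior_quadrature(self):
        # 2 tips in the same state: every configuration has positive mass;
        # RJ frequencies must match the brute-force quadrature posterior
        tree = Phylogeny.from_string("(A:1,B:1);")
        col = TraitColumn({"A": {ABSENCE}, "B": {ABSENCE}})
        hyper = GammaHyper(mean_bounds=(0.5, 0.5), shape_bounds=(2.0, 2.0),
                           shape=2.0, rate=4.0)
        oracle = _tiny_posterior_oracle(tree, col, hyper)
        # pin the chain's hyperprior to the oracle's fixed gamma(2, mean 0.5)
        cfg = ChainConfig(n_generations=60_000, burn_in=2_000, sample_interval=20,
                          n_chains=1, seed=7, hyper_interval=(0.5, 0.0),
                          shape_bounds=(2.0, 2.0))
        res = run_chain(tree, col, cfg, states=(ABSENCE, SCALES))
        n = len(res.samples)
        for sig, expected in oracle.items():
            observed = sum(1 for s in res.samples if s.signature == sig) / n
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < max(3 * se, 0.02), (
                sig, observed, expected
            )

    def test_multi_chain_convergence_and_pooling(self, balanced_tree):
        col = TraitColumn(
            {"A": {ABSENCE}, "B": {ABSENCE}, "C": {SCALES}, "D": {SCALES}}
        )
        cfg = ChainConfig(n_generations=3000, burn_in=500, sample_interval=25,
                          n_chains=3, seed=1, hyper_interval=(0.5, 0.25))
        res = run_chains(balanced_tree, col, cfg, states=(ABSENCE, SCALES))
        assert len(res.chains) == 3
        assert len(res.pooled) > 0
        assert res.max_lnhm_diff >= 0.0
        per_chain = {c.seed for c in res.chains}
        assert per_chain == {1, 2, 3}

    def test_model_sample_validation(self):
        cfg = RateConfiguration.single_class((ABSENCE, SCALES), 1.0)
        with pytest.raises(ValueError):
            ModelSample(cfg, float("nan"), np.array([0.5, 0.5]), 1)
        with pytest.raises(ValueError):
            ModelSample(cfg, -1.0, np.array([0.6, 0.6]), 1)


class TestChainConfig:
    def test_bad_burn_in(self):
        with pytest.raises(ValueError):
            ChainConfig(n_generations=100, burn_in=100)

    def test_paper_scale_defaults(self):
        cfg = ChainConfig.paper_scale()
        assert cfg.burn_in == 500_000
        assert cfg.sample_interval == 100_000
        assert cfg.n_chains == 4
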