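"""Rate matrices, transition probabilities, pruning likelihood, ML rates."""

import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plumevol.ctmc import (
    RateConfiguration,
    brute_force_log_likelihood,
    build_rate_matrix,
    log_likelihood,
    ml_rates,
    ordered_pairs,
    root_marginals,
    stationary_distribution,
    transition_matrices,
    transition_matrix,
)
from plumevol.phylo import Phylogeny
from plumevol.states import ABSENCE, BARS, SCALES, SPOTS, STATE_ORDER
from plumevol.traits import TraitColumn


class TestRateConfiguration:
    def test_all_zero(self):
        cfg = RateConfiguration.all_zero(STATE_ORDER)
        assert cfg.n_pairs == 12 and cfg.n_classes == 0
        assert np.allclose(build_rate_matrix(cfg), 0.0)

    def test_single_class_row_closure(self):
        cfg = RateConfiguration.single_class(STATE_ORDER, 1.0)
        Q = build_rate_matrix(cfg)
        assert np.allclose(np.diag(Q), -3.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_single_nonzero_pair(self):
        cfg = RateConfiguration.from_rates(STATE_ORDER, {(ABSENCE, BARS): 2.0})
        Q = build_rate_matrix(cfg)
        i, j = STATE_ORDER.index(ABSENCE), STATE_ORDER.index(BARS)
        assert Q[i, j] == 2.0 and Q[i, i] == -2.0
        assert np.count_nonzero(Q) == 2

    def test_missing_pair_rejected(self):
        pairs = ordered_pairs(STATE_ORDER)
        assign = {p: None for p in pairs[:-1]}
        with pytest.raises(ValueError, match="cover all ordered pairs"):
            RateConfiguration(STATE_ORDER, assign, {})

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConfiguration.single_class(STATE_ORDER, 0.0)

    def test_signature_canonical_under_class_relabeling(self):
        pairs = ordered_pairs(STATE_ORDER)
        a = {p: 7 if i % 2 else 3 for i, p in enumerate(pairs)}
        b = {p: 0 if i % 2 else 1 for i, p in enumerate(pairs)}
        c1 = RateConfiguration(STATE_ORDER, a, {3: 1.0, 7: 2.0})
        c2 = RateConfiguration(STATE_ORDER, b, {1: 5.0, 0: 0.3})
        assert c1.signature() == c2.signature()


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(RateConfiguration.single_class(STATE_ORDER, 2.0))
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(4))

    def test_two_state_symmetric_closed_form(self, two_state):
        # stay probability (1 + exp(-2qt))/2 = 0.75 at q=1, t=ln2/2
        Q = build_rate_matrix(RateConfiguration.single_class(two_state, 1.0))
        P = transition_matrix(Q, math.log(2) / 2)
        assert P[0, 0] == pytest.approx(0.75, abs=1e-12)
        assert P[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(RateConfiguration.single_class(STATE_ORDER, 1.0))
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)

    def test_long_time_rows_reach_stationary_vector(self):
        rng = np.random.default_rng(5)
        rates = {p: float(rng.gamma(2.0)) for p in ordered_pairs(STATE_ORDER)}
        Q = build_rate_matrix(RateConfiguration.from_rates(STATE_ORDER, rates))
        pi = stationary_distribution(Q)
        P = transition_matrix(Q, 500.0)
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-8)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_semigroup_property(self, seed):
        rng = np.random.default_rng(seed)
        rates = {
            p: float(rng.gamma(1.0))
            for p in ordered_pairs(STATE_ORDER)
            if rng.uniform() < 0.7
        }
        cfg_rates = {p: r for p, r in rates.items() if r > 0}
        if not cfg_rates:
            return
        Q = build_rate_matrix(RateConfiguration.from_rates(STATE_ORDER, cfg_rates))
        s, t = rng.uniform(0, 2, size=2)
        lhs = transition_matrix(Q, s + t)
        rhs = transition_matrix(Q, s) @ transition_matrix(Q, t)
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_batched_matches_single(self):
        Q = build_rate_matrix(
            RateConfiguration.from_rates(
                STATE_ORDER, {(ABSENCE, BARS): 1.0, (BARS, SCALES): 0.5}
            )
        )
        ts = np.array([0.0, 0.3, 1.7, 10.0])
        batched = transition_matrices(Q, ts)
        for i, t in enumerate(ts):
            assert np.abs(batched[i] - transition_matrix(Q, t)).max() < 1e-9


class TestLogLikelihood:
    def test_two_tip_symmetric_closed_form(self, cherry_tree, two_state):
        Q = build_rate_matrix(RateConfiguration.single_class(two_state, 1.0))
        col = TraitColumn({"A": {ABSENCE}, "B": {ABSENCE}})
        ll = log_likelihood(cherry_tree, col, Q, states=two_state)
        # 0.5 * (0.75^2 + 0.25^2) = 0.3125
        assert ll == pytest.approx(math.log(0.3125), abs=1e-12)

    def test_fully_ambiguous_tips_have_likelihood_one(self, balanced_tree):
        Q = build_rate_matrix(RateConfiguration.single_class(STATE_ORDER, 0.7))
        col = TraitColumn({t: set(STATE_ORDER) for t in "ABCD"})
        assert log_likelihood(balanced_tree, col, Q) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_character_matches_point_prior(self, balanced_tree):
        Q = build_rate_matrix(RateConfiguration.all_zero(STATE_ORDER))
        col = TraitColumn({t: {BARS} for t in "ABCD"})
        prior = np.zeros(4)
        prior[STATE_ORDER.index(BARS)] = 1.0
        assert log_likelihood(balanced_tree, col, Q, prior) == pytest.approx(0.0)

    def test_taxon_mismatch_names_taxa(self, balanced_tree):
        col = TraitColumn({t: {BARS} for t in "ABC"})
        with pytest.raises(ValueError, match="D"):
            log_likelihood(balanced_tree, col, np.zeros((4, 4)))

    def test_likelihood_invariant_to_state_relabeling(self, balanced_tree):
        rates = {(ABSENCE, BARS): 0.8, (BARS, ABSENCE): 0.2, (BARS, SCALES): 0.5}
        col_states = {"A": {ABSENCE}, "B": {BARS}, "C": {SCALES}, "D": {BARS}}
        base_order = (ABSENCE, BARS, SCALES)
        perm_order = (SCALES, ABSENCE, BARS)
        ll1 = log_likelihood(
            balanced_tree,
            TraitColumn(dict(col_states)),
            build_rate_matrix(
                RateConfiguration.from_rates(base_order, rates), base_order
            ),
            states=base_order,
        )
        ll2 = log_likelihood(
            balanced_tree,
            TraitColumn(dict(col_states)),
            build_rate_matrix(
                RateConfiguration.from_rates(perm_order, rates), perm_order
            ),
            states=perm_order,
        )
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_pruning_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for trial in range(40):
            k = int(rng.integers(2, 5))
            states = STATE_ORDER[:k]
            n = int(rng.integers(2, 7))
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=random.Random(trial),
            )
            for i, leaf in enumerate(tree.leaf_node_iter(), 1):
                leaf.taxon.label = f"t{i}"
            phylo = Phylogeny(tree)
            rates = {
                p: float(rng.gamma(1.0))
                for p in ordered_pairs(states)
                if rng.uniform() < 0.7
            }
            if not rates:
                continue
            Q = build_rate_matrix(RateConfiguration.from_rates(states, rates), states)
            col = TraitColumn(
                {
                    t: set(
                        s for s in states if rng.uniform() < 0.5
                    ) or {states[0]}
                    for t in phylo.taxa
                }
            )
            ll = log_likelihood(phylo, col, Q, states=states)
            oracle = brute_force_log_likelihood(phylo, col, Q, states=states)
            assert ll == pytest.approx(oracle, abs=1e-10)
            checked += 1
        assert checked >= 30


class TestRootMarginals:
    def test_frozen_character_gives_point_mass(self, balanced_tree):
        Q = build_rate_matrix(RateConfiguration.all_zero(STATE_ORDER))
        col = TraitColumn({t: {SPOTS} for t in "ABCD"})
        probs = root_marginals(balanced_tree, col, Q)
        expect = np.zeros(4)
        expect[STATE_ORDER.index(SPOTS)] = 1.0
        assert np.allclose(probs, expect)

    def test_saturated_branches_give_uniform(self, two_state):
        t = Phylogeny.from_string("(A:500,B:500,C:500);")
        Q = build_rate_matrix(RateConfiguration.single_class(two_state, 1.0))
        col = TraitColumn({"A": {ABSENCE}, "B": {SCALES}, "C": {ABSENCE}})
        probs = root_marginals(t, col, Q, states=two_state)
        assert np.allclose(probs, [0.5, 0.5], atol=1e-6)

    def test_impossible_data_rejected(self, balanced_tree):
        Q = build_rate_matrix(RateConfiguration.all_zero(STATE_ORDER))
        col = TraitColumn({"A": {BARS}, "B": {SPOTS}, "C": {BARS}, "D": {BARS}})
        with pytest.raises(ValueError, match="zero likelihood"):
            root_marginals(balanced_tree, col, Q)

    def test_sums_to_one(self, balanced_tree):
        Q = build_rate_matrix(RateConfiguration.single_class(STATE_ORDER, 0.4))
        col = TraitColumn({"A": {BARS}, "B": {SPOTS}, "C": {BARS}, "D": {ABSENCE}})
        assert root_marginals(balanced_tree, col, Q).sum() == pytest.approx(1.0)


class TestMlRates:
    def test_identical_tips_drive_rate_to_zero(self, cherry_tree, two_state):
        skeleton = RateConfiguration.single_class(two_state, 1.0)
        col = TraitColumn({"A": {ABSENCE}, "B": {ABSENCE}})
        rates, ll = ml_rates(cherry_tree, col, skeleton)
        assert rates[0] < 1e-4
        # at q -> 0 the likelihood tends to the stationary bound 1/2
        assert ll == pytest.approx(math.log(0.5), abs=1e-3)

    def test_duplicated_class_equals_single_parameter_fit(self, balanced_tree):
        col = TraitColumn({"A": {ABSENCE}, "B": {BARS}, "C": {BARS}, "D": {SPOTS}})
        single = RateConfiguration.single_class(STATE_ORDER, 1.0)
        pairs = ordered_pairs(STATE_ORDER)
        twelve = RateConfiguration(
            STATE_ORDER, {p: 0 for p in pairs}, {0: 1.0}
        )
        r1, ll1 = ml_rates(balanced_tree, col, single)
        r2, ll2 = ml_rates(balanced_tree, col, twelve)
        assert ll1 == pytest.approx(ll2, abs=1e-6)
        assert r1[0] == pytest.approx(r2[0], rel=1e-3)

    def test_recovers_simulated_rate_scale(self):
        # moderate-size simulation: the ML estimate of a single shared rate
        # should land within a factor of two of the generating value
        from plumevol.simulate import ScenarioSpec, generate_scenario

        truth = RateConfiguration.single_class((ABSENCE, SCALES), 1.0)
        spec = ScenarioSpec(
            n_tips=150, true_config=truth, root_state=ABSENCE,
            birth_rate=1.0, low_support_fraction=0.0, seed=7,
        )
        tree, col = generate_scenario(spec)
        rates, _ = ml_rates(tree, col, truth)
        assert 0.5 < rates[0] < 2.0
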