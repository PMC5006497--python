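"""Synthetic trees and trait data with the structure the analysis assumes.

The generator produces birth–death (or Yule) trees conditioned on a tip
count, sprinkles low-support internal branches, evolves a four-state
pattern character forward under a sparse rate configuration, and injects
missing ("mottled") tips — everything the inference pipeline consumes,
with a known generative truth for recovery tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
import numpy as np
from dendropy.model import birthdeath

from .ctmc import RateConfiguration, build_rate_matrix, transition_matrices
from .phylo import Phylogeny
from .states import ABSENCE, BARS, FULL_SET, SCALES, SPOTS, STATE_ORDER
from .traits import TraitColumn


class InvalidScenarioError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """Complete description of one synthetic data-generating scenario."""

    n_tips: int
    true_config: RateConfiguration
    root_state: str = ABSENCE
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    low_support_fraction: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0
    name: str = "custom"
    #: minimum unambiguous tips per state; nonzero values make the generator
    #: redraw until every state segregates, emulating empirical tables in
    #: which all pattern states are represented
    min_state_tips: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise InvalidScenarioError("n_tips must be >= 3")
        if self.tree_model not in ("yule", "birth_death"):
            raise InvalidScenarioError(f"unknown tree model {self.tree_model!r}")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise InvalidScenarioError("need birth_rate > 0 and death_rate >= 0")
        if self.tree_model == "yule" and self.death_rate != 0:
            raise InvalidScenarioError("yule model requires death_rate == 0")
        for frac, label in (
            (self.low_support_fraction, "low_support_fraction"),
            (self.missing_rate, "missing_rate"),
        ):
            if not (0.0 <= frac <= 1.0):
                raise InvalidScenarioError(f"{label} must lie in [0, 1]")
        if self.root_state not in self.true_config.states:
            raise InvalidScenarioError(
                f"root state {self.root_state!r} outside state space "
                f"{self.true_config.states}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_tips": self.n_tips,
            "tree_model": self.tree_model,
            "birth_rate": self.birth_rate,
            "death_rate": self.death_rate,
            "low_support_fraction": self.low_support_fraction,
            "missing_rate": self.missing_rate,
            "root_state": self.root_state,
            "seed": self.seed,
            "true_rates": {
                f"{a}->{b}": self.true_config.rate_of((a, b))
                for (a, b) in sorted(self.true_config.assignment)
            },
            "zero_pairs": [
                f"{a}->{b}" for (a, b) in sorted(self.true_config.zero_pairs)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def simulate_tree(spec: ScenarioSpec) -> Phylogeny:
    """Forward birth–death simulation conditioned on the extant tip count.

    Tips are labeled ``sp1..spN`` in leaf order; internal branches get
    support values: a ``low_support_fraction`` share drawn uniform(0.5,
    0.95] and the rest uniform(0.96, 1.0), reflecting that only the 0.95
    collapse threshold — not a support distribution — is part of the
    analysis design.
    """
    tree = birthdeath.birth_death_tree(
        birth_rate=spec.birth_rate,
        death_rate=spec.death_rate,
        num_extant_tips=spec.n_tips,
        rng=random.Random(spec.seed),
        repeat_until_success=True,
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i}"
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-8
    phylo = Phylogeny(tree)

    rng = np.random.default_rng(spec.seed)
    internals = list(phylo.internal_nodes())
    n_low = int(round(spec.low_support_fraction * len(internals)))
    low_idx = set(rng.choice(len(internals), size=n_low, replace=False)) if n_low else set()
    for i, node in enumerate(internals):
        if i in low_idx:
            node.support = float(rng.uniform(0.5, 0.95))
        else:
            node.support = float(rng.uniform(0.96, 1.0))
    return phylo


def simulate_traits(
    tree: Phylogeny,
    config: RateConfiguration,
    root_state: str,
    seed: int = 0,
    method: str = "jump",
) -> TraitColumn:
    """Evolve the character forward along the tree under Q(config).

    ``method="jump"`` samples waiting times and jumps (exact Gillespie
    path); ``method="matrix"`` samples each child state from the branch's
    transition matrix exp(Qt) — distributionally identical at the nodes,
    kept as an internal cross-check.
    """
    states = config.states
    if root_state not in states:
        raise ValueError(f"root state {root_state!r} not in state space {states}")
    index = {s: i for i, s in enumerate(states)}
    Q = build_rate_matrix(config)
    rng = np.random.default_rng(seed)
    node_state: dict[int, int] = {}
    root = tree.tree.seed_node
    node_state[id(root)] = index[root_state]

    if method == "matrix":
        nodes = list(tree.tree.preorder_node_iter())
        lengths = np.array([n.edge.length or 0.0 for n in nodes])
        P = transition_matrices(Q, lengths)
        for i, node in enumerate(nodes):
            if node is root:
                continue
            parent = node_state[id(node.parent_node)]
            node_state[id(node)] = int(rng.choice(len(states), p=P[i][parent]))
    elif method == "jump":
        for node in tree.tree.preorder_node_iter():
            if node is root:
                continue
            s = node_state[id(node.parent_node)]
            t_left = node.edge.length or 0.0
            while True:
                out_rate = -Q[s, s]
                if out_rate <= 0.0:
                    break
                wait = rng.exponential(1.0 / out_rate)
                if wait >= t_left:
                    break
                t_left -= wait
                probs = Q[s].copy()
                probs[s] = 0.0
                probs /= probs.sum()
                s = int(rng.choice(len(states), p=probs))
            node_state[id(node)] = s
    else:
        raise ValueError(f"unknown simulation method {method!r}")

    assignments = {
        leaf.taxon.label: frozenset({states[node_state[id(leaf)]]})
        for leaf in tree.tree.leaf_node_iter()
    }
    return TraitColumn(assignments, name="simulated")


def inject_missing(
    column: TraitColumn, missing_rate: float, seed: int = 0
) -> TraitColumn:
    """Independently replace each taxon by the full ambiguity set.

    Emulates mottled plumage scored as unknown: the taxon stays on the tree
    but constrains nothing.
    """
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    assignments = {}
    for taxon in column.taxa:
        if rng.uniform() < missing_rate:
            assignments[taxon] = FULL_SET
        else:
            assignments[taxon] = column[taxon]
    return TraitColumn(assignments, name=column.name)


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[Phylogeny, TraitColumn]:
    """Tree + trait column for a scenario (tree, traits, then missingness).

    With ``min_state_tips > 0`` the draw is repeated under derived seeds
    until every state of the true configuration's space is observed
    unambiguously in at least that many tips — a scenario in which some
    pattern never evolved cannot inform the transitions involving it.
    """
    from collections import Counter
    from dataclasses import replace

    attempt = spec
    for retry in range(500):
        tree = simulate_tree(attempt)
        column = simulate_traits(
            tree, attempt.true_config, attempt.root_state, seed=attempt.seed + 1
        )
        if attempt.missing_rate > 0:
            column = inject_missing(column, attempt.missing_rate, seed=attempt.seed + 2)
        if spec.min_state_tips <= 0:
            return tree, column
        freq = Counter(
            next(iter(s)) for s in column.assignments.values() if len(s) == 1
        )
        if all(
            freq.get(s, 0) >= spec.min_state_tips
            for s in spec.true_config.states
        ):
            return tree, column
        attempt = replace(spec, seed=(spec.seed + 10007 * (retry + 1)) % (2**31 - 1))
    raise InvalidScenarioError(
        f"could not realize {spec.min_state_tips} tips per state in 500 draws"
    )


# ---------------------------------------------------------------------
# presets


def _chain_config() -> RateConfiguration:
    """Sparse truth: absence→bars→scales→spots with bidirectional bars↔scales.

    Rates are calibrated purely against the forward simulator so that on a
    unit-birth-rate Yule tree of 200 tips the ancestral state stays a
    plurality while each derived pattern segregates at a realistic minority
    frequency: gaining patterning from the unpatterned ancestor is slow
    (0.15/unit), motif switching once patterning exists is faster (0.3),
    and scaled plumage converts onward to spots at a similar pace (0.35).
    Three rate classes, so recovery also exercises the class partition.
    """
    return RateConfiguration.from_rates(
        STATE_ORDER,
        {
            (ABSENCE, BARS): 0.15,
            (BARS, SCALES): 0.3,
            (SCALES, BARS): 0.3,
            (SCALES, SPOTS): 0.35,
        },
    )


def _preset_constraint_chain(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        name="constraint_chain",
        n_tips=200,
        true_config=_chain_config(),
        root_state=ABSENCE,
        tree_model="yule",
        birth_rate=1.0,
        low_support_fraction=0.1,
        missing_rate=0.1,
        seed=seed,
        min_state_tips=20,
    )


def _preset_full_model(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        name="full_model",
        n_tips=200,
        true_config=RateConfiguration.single_class(STATE_ORDER, 0.1),
        root_state=ABSENCE,
        tree_model="yule",
        birth_rate=1.0,
        low_support_fraction=0.1,
        missing_rate=0.1,
        seed=seed,
    )


def _preset_no_evolution(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        name="no_evolution",
        n_tips=100,
        true_config=RateConfiguration.all_zero(STATE_ORDER),
        root_state=ABSENCE,
        tree_model="yule",
        birth_rate=1.0,
        low_support_fraction=0.0,
        missing_rate=0.0,
        seed=seed,
    )


PRESETS = {
    "constraint_chain": _preset_constraint_chain,
    "full_model": _preset_full_model,
    "no_evolution": _preset_no_evolution,
}


def scenario_preset(name: str, seed: int = 0) -> ScenarioSpec:
    """A fully populated scenario from the documented preset registry."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return PRESETS[name](seed)
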