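"""Multistate continuous-time Markov model on a phylogeny.

A rate configuration assigns each ordered state pair either to ZERO (the
transition does not occur) or to a rate class; pairs sharing a class share
one positive rate.  The likelihood of a trait column is evaluated by
Felsenstein pruning with ambiguous tips contributing a partial likelihood
of 1 for every allowed state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo import Phylogeny
from .traits import TraitColumn

Pair = tuple[str, str]

ZERO = None  # sentinel for "transition does not occur"


def ordered_pairs(states: Sequence[str]) -> list[Pair]:
    """All k(k-1) ordered state pairs in canonical row-major order."""
    return [(a, b) for a in states for b in states if a != b]


@dataclass
class RateConfiguration:
    """Zero/rate-class assignment over ordered state pairs, with class rates."""

    states: tuple[str, ...]
    assignment: dict[Pair, int | None]
    class_rates: dict[int, float]

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        expected = set(ordered_pairs(self.states))
        if set(self.assignment) != expected:
            missing = expected - set(self.assignment)
            extra = set(self.assignment) - expected
            raise ValueError(
                f"assignment must cover all ordered pairs; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        used = {c for c in self.assignment.values() if c is not None}
        if used != set(self.class_rates):
            raise ValueError(
                f"class ids {sorted(used)} do not match rates {sorted(self.class_rates)}"
            )
        for cid, rate in self.class_rates.items():
            if not (rate > 0 and math.isfinite(rate)):
                raise ValueError(f"class {cid} rate must be positive finite, got {rate}")

    # -- constructors --------------------------------------------------
    @classmethod
    def all_zero(cls, states: Sequence[str]) -> "RateConfiguration":
        return cls(tuple(states), {p: ZERO for p in ordered_pairs(states)}, {})

    @classmethod
    def single_class(cls, states: Sequence[str], rate: float) -> "RateConfiguration":
        return cls(
            tuple(states), {p: 0 for p in ordered_pairs(states)}, {0: float(rate)}
        )

    @classmethod
    def from_rates(
        cls, states: Sequence[str], rates: Mapping[Pair, float]
    ) -> "RateConfiguration":
        """Build from per-pair rates; 0 means ZERO, equal rates share a class."""
        assignment: dict[Pair, int | None] = {}
        class_rates: dict[int, float] = {}
        value_to_class: dict[float, int] = {}
        for pair in ordered_pairs(states):
            rate = float(rates.get(pair, 0.0))
            if rate == 0.0:
                assignment[pair] = ZERO
            else:
                if rate not in value_to_class:
                    value_to_class[rate] = len(value_to_class)
                    class_rates[value_to_class[rate]] = rate
                assignment[pair] = value_to_class[rate]
        return cls(tuple(states), assignment, class_rates)

    # -- queries -------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.assignment)

    @property
    def free_pairs(self) -> list[Pair]:
        return [p for p in ordered_pairs(self.states) if self.assignment[p] is not None]

    @property
    def zero_pairs(self) -> list[Pair]:
        return [p for p in ordered_pairs(self.states) if self.assignment[p] is None]

    @property
    def n_classes(self) -> int:
        return len(self.class_rates)

    def class_members(self) -> dict[int, list[Pair]]:
        out: dict[int, list[Pair]] = {c: [] for c in self.class_rates}
        for pair in ordered_pairs(self.states):
            cid = self.assignment[pair]
            if cid is not None:
                out[cid].append(pair)
        return out

    def rate_of(self, pair: Pair) -> float:
        cid = self.assignment[pair]
        return 0.0 if cid is None else self.class_rates[cid]

    def signature(self) -> str:
        """Canonical model signature: classes renumbered by first appearance.

        Two configurations share a signature iff they have the same ZERO set
        and the same partition of free pairs into shared-rate classes.
        """
        renumber: dict[int, int] = {}
        tokens: list[str] = []
        for pair in ordered_pairs(self.states):
            cid = self.assignment[pair]
            if cid is None:
                tokens.append("Z")
            else:
                if cid not in renumber:
                    renumber[cid] = len(renumber)
                tokens.append(str(renumber[cid]))
        return ",".join(tokens)

    def copy(self) -> "RateConfiguration":
        return RateConfiguration(
            self.states, dict(self.assignment), dict(self.class_rates)
        )


def build_rate_matrix(
    config: RateConfiguration, states: Sequence[str] | None = None
) -> np.ndarray:
    """Instantaneous rate matrix Q with rows closed to zero."""
    states = tuple(states) if states is not None else config.states
    if set(states) != set(config.states):
        raise ValueError("state list does not match configuration")
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((k, k))
    for (a, b), cid in config.assignment.items():
        if cid is not None:
            Q[index[a], index[b]] = config.class_rates[cid]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(k)] = -Q.sum(axis=1)
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length (scaling-and-squaring)."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    return _clean_probability_matrix(P)


def _clean_probability_matrix(P: np.ndarray) -> np.ndarray:
    if P.min() < -1e-9:
        raise FloatingPointError(f"transition probability {P.min()} < 0")
    P = np.clip(P, 0.0, None)
    rows = P.sum(axis=-1, keepdims=True)
    if np.any(np.abs(rows - 1.0) > 1e-8):
        raise FloatingPointError("transition matrix rows do not sum to 1")
    return P / rows


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Qt) for a whole vector of branch lengths at once.

    Fast path: one eigendecomposition of Q, then a vectorized reconstruction
    over branches; validated by row-sum and positivity checks with a
    per-branch scaling-and-squaring fallback when Q is defective or the
    eigenbasis is ill-conditioned.
    """
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("branch lengths must be >= 0")
    k = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        cond = np.linalg.cond(U)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        Uinv = np.linalg.inv(U)
        ew = np.exp(np.outer(ts, w))  # (B, k)
        P = np.einsum("ij,bj,jk->bik", U, ew, Uinv)
        P = np.ascontiguousarray(P.real)
        if P.min() < -1e-8 or np.any(np.abs(P.sum(axis=2) - 1.0) > 1e-8):
            raise np.linalg.LinAlgError("eigen reconstruction inaccurate")
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P
    except np.linalg.LinAlgError:
        out = np.empty((len(ts), k, k))
        for i, t in enumerate(ts):
            out[i] = transition_matrix(Q, float(t))
        return out


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary probabilities of an irreducible rate matrix (left null space)."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------
# pruning


class PruningContext:
    """Preindexed tree + tip data for repeated likelihood evaluation.

    Built once per (tree, trait column, state list); every subsequent call
    only needs a rate matrix, which is the hot path inside MCMC.
    """

    def __init__(
        self,
        tree: Phylogeny,
        column: TraitColumn,
        states: Sequence[str],
    ) -> None:
        self.states = tuple(states)
        k = len(self.states)
        state_index = {s: i for i, s in enumerate(self.states)}
        tips = set(tree.taxa)
        missing = sorted(set(column.taxa) - tips)
        absent = sorted(tips - set(column.taxa))
        if missing or absent:
            raise ValueError(
                f"taxon mismatch between tree and traits: traits-only={missing}, "
                f"tree-only={absent}"
            )

        nodes = list(tree.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        node_id = {id(n): i for i, n in enumerate(nodes)}
        self.root_index = node_id[id(tree.tree.seed_node)]
        self.branch_lengths = np.array(
            [n.edge.length if n.edge.length is not None else 0.0 for n in nodes]
        )
        self.children: list[list[int]] = [
            [node_id[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        self.postorder_internal = [
            i for i, n in enumerate(nodes) if not n.is_leaf()
        ]
        self.tip_data = np.zeros((self.n_nodes, k))
        for i, n in enumerate(nodes):
            if n.is_leaf():
                allowed = column[n.taxon.label]
                for s in allowed:
                    if s in state_index:
                        self.tip_data[i, state_index[s]] = 1.0
                if self.tip_data[i].sum() == 0:
                    raise ValueError(
                        f"tip {n.taxon.label!r} allows no state in the modeled "
                        f"space {self.states}"
                    )

    # -- likelihood ----------------------------------------------------
    def _root_partial(self, Q: np.ndarray) -> tuple[np.ndarray, float]:
        """Conditional likelihood vector at the root plus log scaling factor."""
        P = transition_matrices(Q, self.branch_lengths)
        partial = self.tip_data.copy()
        log_scale = 0.0
        for i in self.postorder_internal:
            acc = None
            for c in self.children[i]:
                msg = P[c] @ partial[c]
                acc = msg if acc is None else acc * msg
            m = acc.max()
            if m <= 0.0:
                return np.zeros_like(acc), -np.inf
            acc /= m
            log_scale += math.log(m)
            partial[i] = acc
        return partial[self.root_index], log_scale

    def log_likelihood(
        self, Q: np.ndarray, root_prior: np.ndarray | None = None
    ) -> float:
        prior = self._check_prior(root_prior)
        root, log_scale = self._root_partial(Q)
        total = float(prior @ root)
        if total <= 0.0:
            return -np.inf
        return math.log(total) + log_scale

    def root_marginals(
        self, Q: np.ndarray, root_prior: np.ndarray | None = None
    ) -> np.ndarray:
        prior = self._check_prior(root_prior)
        root, _ = self._root_partial(Q)
        weighted = prior * root
        total = weighted.sum()
        if total <= 0.0:
            raise ValueError("data have zero likelihood under this model")
        return weighted / total

    def _check_prior(self, root_prior: np.ndarray | None) -> np.ndarray:
        k = len(self.states)
        if root_prior is None:
            return np.full(k, 1.0 / k)
        prior = np.asarray(root_prior, dtype=float)
        if prior.shape != (k,) or abs(prior.sum() - 1.0) > 1e-8 or prior.min() < 0:
            raise ValueError("root prior must be a length-k probability vector")
        return prior


def log_likelihood(
    tree: Phylogeny,
    column: TraitColumn,
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
    states: Sequence[str] | None = None,
) -> float:
    """Pruning log-likelihood of one trait column under rate matrix Q."""
    from .states import STATE_ORDER

    states = tuple(states) if states is not None else STATE_ORDER[: Q.shape[0]]
    return PruningContext(tree, column, states).log_likelihood(Q, root_prior)


def root_marginals(
    tree: Phylogeny,
    column: TraitColumn,
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
    states: Sequence[str] | None = None,
) -> np.ndarray:
    """Posterior state probabilities at the root given tips and Q."""
    from .states import STATE_ORDER

    states = tuple(states) if states is not None else STATE_ORDER[: Q.shape[0]]
    return PruningContext(tree, column, states).root_marginals(Q, root_prior)


# ---------------------------------------------------------------------
# maximum likelihood rates


def ml_rates(
    tree: Phylogeny,
    column: TraitColumn,
    skeleton: RateConfiguration,
    root_prior: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[dict[int, float], float]:
    """Maximize the likelihood over positive class rates of a skeleton.

    Optimization runs on log-rates (multi-start L-BFGS-B) so boundary
    optima at rate -> 0 are reachable as large negative log-rates.
    """
    class_ids = sorted(skeleton.class_rates)
    if not class_ids:
        raise ValueError("skeleton has no free rate class")
    ctx = PruningContext(tree, column, skeleton.states)
    # characteristic scale: one expected event per mean root-to-tip path
    mean_height = float(np.sum(ctx.branch_lengths)) / max(1, len(ctx.branch_lengths))
    scale = 1.0 / max(mean_height * 4.0, 1e-6)

    def neg_loglik(x: np.ndarray) -> float:
        cfg = skeleton.copy()
        cfg.class_rates = {c: float(np.exp(v)) for c, v in zip(class_ids, x)}
        Q = build_rate_matrix(cfg)
        ll = ctx.log_likelihood(Q, root_prior)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.full(len(class_ids), math.log(scale * f)) for f in (0.1, 1.0, 10.0)]
    while len(starts) < n_starts:
        starts.append(np.log(scale) + rng.normal(0.0, 2.0, size=len(class_ids)))
    best_x, best_val = None, np.inf
    bounds = [(-15.0, 8.0)] * len(class_ids)
    for x0 in starts[:max(n_starts, 3)]:
        res = minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if best_x is None or not np.isfinite(best_val):
        raise RuntimeError("likelihood not finite anywhere in the search region")
    rates = {c: float(np.exp(v)) for c, v in zip(class_ids, best_x)}
    return rates, -best_val


def empirical_bayes_interval(
    tree: Phylogeny,
    column: TraitColumn,
    states: Sequence[str],
    root_prior: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean, sd) of the per-pair maximum-likelihood rates.

    Fits the saturated model in which every ordered pair has its own rate
    class and summarizes the fitted rates; the pair is used to center the
    gamma hyperprior on class rates.

    Rates that the optimizer pushes to the lower boundary (transitions the
    data do not want at all) are excluded from the summary: the hyperprior
    describes the magnitude of rates that are genuinely non-zero, and
    letting boundary zeros drag its center down would blur the reversible
    jump's separation between free and zero transitions.
    """
    states = tuple(states)
    pairs = ordered_pairs(states)
    skeleton = RateConfiguration(
        states,
        {p: i for i, p in enumerate(pairs)},
        {i: 1.0 for i in range(len(pairs))},
    )
    rates, _ = ml_rates(tree, column, skeleton, root_prior=root_prior, seed=seed)
    values = np.array(list(rates.values()))
    boundary = max(1e-4, 0.01 * float(values.max()))
    nonzero = values[values > boundary]
    if nonzero.size == 0:
        nonzero = values
    mean = float(nonzero.mean())
    sd = float(nonzero.std())
    if sd == 0.0 or not np.isfinite(sd):
        sd = mean / 2.0 if mean > 0 else 0.5
    return mean, sd


def brute_force_log_likelihood(
    tree: Phylogeny,
    column: TraitColumn,
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
    states: Sequence[str] | None = None,
) -> float:
    """Likelihood by explicit summation over all internal-node state maps.

    Exponential in the internal node count; an independent oracle for tiny
    trees, never a production path.
    """
    from .states import STATE_ORDER

    states = tuple(states) if states is not None else STATE_ORDER[: Q.shape[0]]
    ctx = PruningContext(tree, column, states)
    k = len(states)
    prior = ctx._check_prior(root_prior)
    P = transition_matrices(Q, ctx.branch_lengths)
    internals = ctx.postorder_internal
    if not internals:  # degenerate single-node tree
        total = float(prior @ ctx.tip_data[ctx.root_index])
        return math.log(total) if total > 0 else -np.inf
    tips = [i for i in range(ctx.n_nodes) if i not in internals]
    parent = [-1] * ctx.n_nodes
    for i in internals:
        for c in ctx.children[i]:
            parent[c] = i
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        like = prior[assign[ctx.root_index]]
        for i in internals:
            if i != ctx.root_index:
                like *= P[i][assign[parent[i]], assign[i]]
        for t in tips:
            like *= float(P[t][assign[parent[t]]] @ ctx.tip_data[t])
        total += like
    return math.log(total) if total > 0 else -np.inf
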