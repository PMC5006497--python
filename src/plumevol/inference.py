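"""Multimodel statistics over the posterior sample of rate configurations.

A "unique model" is a signature: which ordered pairs are ZERO plus how the
free pairs partition into shared-rate classes.  The configuration space for
n pairs therefore has Σ_z C(n, z)·B(n−z) = B(n+1) members (choose the zero
set, then partition the rest; B are the Bell numbers).  Prior odds for a
model account for its complexity class — all configurations with the same
number of zero transitions — so Bayes factors compare each model's posterior
visit frequency against how much of the uniform configuration prior its
complexity class occupies.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ctmc import Pair, ordered_pairs
from .rjmcmc import ModelSample


# ---------------------------------------------------------------------
# configuration-space counting


@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """Exact Bell number B(n) via the Bell-triangle recurrence."""
    if n < 0:
        raise ValueError("Bell numbers need n >= 0")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def model_space_size(n_pairs: int) -> int:
    """Number of distinct configurations over ``n_pairs`` ordered pairs.

    Σ_{z=0..n} C(n, z)·B(n−z); identically B(n+1).
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    return sum(
        math.comb(n_pairs, z) * bell_number(n_pairs - z)
        for z in range(n_pairs + 1)
    )


def prior_probability(
    n_pairs: int, n_zero: int, mode: str = "complexity"
) -> float:
    """Prior probability of a model under the uniform configuration prior.

    ``"complexity"`` (default): mass of the model's complexity class —
    C(n, z)·B(n−z)/B(n+1), the share of configurations with the same number
    of zero transitions, combining binomial counting of the zero set with
    Bell counting of the free-pair partitions.  ``"uniform"``: every single
    configuration gets 1/B(n+1).
    """
    total = model_space_size(n_pairs)
    if mode == "uniform":
        return 1.0 / total
    if mode == "complexity":
        cls = math.comb(n_pairs, n_zero) * bell_number(n_pairs - n_zero)
        return cls / total
    raise ValueError(f"unknown prior mode {mode!r}")


def bayes_factor(signature_count: int, n_samples: int, prior_prob: float) -> float:
    """Posterior odds over prior odds for one model.

    BF = [p̂/(1−p̂)] / [π/(1−π)] with p̂ the posterior visit fraction; a
    model visited in every sample returns +inf.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not (0 <= signature_count <= n_samples):
        raise ValueError("count must lie in [0, n_samples]")
    if not (0.0 < prior_prob < 1.0):
        raise ValueError("prior probability must lie strictly in (0, 1)")
    p_hat = signature_count / n_samples
    if p_hat == 1.0:
        return math.inf
    posterior_odds = p_hat / (1.0 - p_hat)
    prior_odds = prior_prob / (1.0 - prior_prob)
    return posterior_odds / prior_odds


# ---------------------------------------------------------------------
# marginal probabilities


ModalState = tuple[str, ...]  # one state, or several tied states


def ancestral_mp(
    modal_states: Sequence[ModalState | str],
    states: Sequence[str],
    weights: Sequence[float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-state (MP_not_ancestral, MP_ancestral) over a model collection.

    Each element of ``modal_states`` is a model's modal root state (or a
    tuple of exactly tied states, which share their weight fractionally —
    two tied states contribute 0.5 each).  Weights default to 1 per model;
    visit-weighted tallies pass per-signature visit counts.
    """
    if len(modal_states) == 0:
        raise ValueError("empty model collection")
    if weights is None:
        weights = [1.0] * len(modal_states)
    total = float(sum(weights))
    tally = {s: 0.0 for s in states}
    for modal, w in zip(modal_states, weights):
        group = (modal,) if isinstance(modal, str) else tuple(modal)
        for s in group:
            tally[s] += w / len(group)
    return {s: (1.0 - tally[s] / total, tally[s] / total) for s in states}


def transition_mp(
    occurrences: Sequence[Mapping[Pair, bool]],
    pairs: Sequence[Pair],
    weights: Sequence[float] | None = None,
) -> dict[Pair, tuple[float, float]]:
    """Per-pair (MP_not_occurring, MP_occurring) over a model collection."""
    if len(occurrences) == 0:
        raise ValueError("empty model collection")
    if weights is None:
        weights = [1.0] * len(occurrences)
    total = float(sum(weights))
    tally = {p: 0.0 for p in pairs}
    for occ, w in zip(occurrences, weights):
        for p in pairs:
            if occ[p]:
                tally[p] += w
    return {p: (1.0 - tally[p] / total, tally[p] / total) for p in pairs}


def average_probabilities(
    samples: Sequence[ModelSample],
) -> tuple[dict[str, float], dict[Pair, float]]:
    """Posterior-mean root-state probabilities and per-pair realized rates.

    ZERO pairs contribute a rate of 0, so the per-pair mean mixes over
    models in which the transition does and does not occur.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    states = samples[0].config.states
    pairs = ordered_pairs(states)
    roots = np.mean([s.root_probs for s in samples], axis=0)
    rates = {
        p: float(np.mean([s.config.rate_of(p) for s in samples])) for p in pairs
    }
    return {s: float(v) for s, v in zip(states, roots)}, rates


# ---------------------------------------------------------------------
# summary of a posterior sample


@dataclass
class InferenceSummary:
    """Model-averaged statistics from one pooled posterior sample."""

    states: tuple[str, ...]
    n_samples: int
    signature_counts: dict[str, int]
    signature_bf: dict[str, float]
    top_set: list[str]
    bf_threshold: float
    full_model_bf: float
    ancestral_full: dict[str, tuple[float, float]]
    ancestral_top: dict[str, tuple[float, float]]
    transition_full: dict[Pair, tuple[float, float]]
    transition_top: dict[Pair, tuple[float, float]]
    avg_root_probs: dict[str, float]
    avg_rates: dict[Pair, float]
    prior_mode: str = "complexity"
    name: str = "trait"

    @property
    def n_unique(self) -> int:
        return len(self.signature_counts)

    @property
    def n_top(self) -> int:
        return len(self.top_set)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "n_samples": self.n_samples,
            "n_unique_models": self.n_unique,
            "n_top_models": self.n_top,
            "bf_threshold": self.bf_threshold,
            "full_model_bf": self.full_model_bf,
            "prior_mode": self.prior_mode,
            "ancestral_mp_full": {s: list(v) for s, v in self.ancestral_full.items()},
            "ancestral_mp_top": {s: list(v) for s, v in self.ancestral_top.items()},
            "transition_mp_full": {
                f"{a}->{b}": list(v) for (a, b), v in self.transition_full.items()
            },
            "transition_mp_top": {
                f"{a}->{b}": list(v) for (a, b), v in self.transition_top.items()
            },
            "avg_root_probs": self.avg_root_probs,
            "avg_rates": {f"{a}->{b}": v for (a, b), v in self.avg_rates.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def top_model_set(
    signature_bf: Mapping[str, float], threshold: float = 2.0
) -> list[str]:
    """Signatures with BF >= threshold, best first (positive evidence)."""
    selected = [(bf, sig) for sig, bf in signature_bf.items() if bf >= threshold]
    if not selected:
        import logging

        logging.getLogger(__name__).warning(
            "no model reaches BF >= %s; top model set is empty", threshold
        )
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [sig for _, sig in selected]


def _signature_zero_count(signature: str) -> int:
    return sum(1 for tok in signature.split(",") if tok == "Z")


def modal_root_state(
    root_vectors: Sequence[np.ndarray], states: Sequence[str]
) -> ModalState:
    """Argmax of the mean sampled root vector; exact ties returned together."""
    mean = np.mean(np.asarray(root_vectors, dtype=float), axis=0)
    best = mean.max()
    return tuple(s for s, v in zip(states, mean) if v == best)


def summarize(
    samples: Sequence[ModelSample],
    bf_threshold: float = 2.0,
    prior_mode: str = "complexity",
    name: str = "trait",
) -> InferenceSummary:
    """Full multimodel summary of a pooled posterior sample.

    Marginal probabilities are visit-weighted (every posterior draw counts,
    so models enter in proportion to their posterior probability), reported
    both over the entire posterior sample and cumulated over the top model
    set.
    """
    if len(samples) == 0:
        raise ValueError("no posterior samples")
    states = samples[0].config.states
    pairs = ordered_pairs(states)
    n = len(samples)

    counts: Counter[str] = Counter(s.signature for s in samples)
    by_sig_roots: dict[str, list[np.ndarray]] = defaultdict(list)
    sig_occurs: dict[str, dict[Pair, bool]] = {}
    for s in samples:
        sig = s.signature
        by_sig_roots[sig].append(s.root_probs)
        if sig not in sig_occurs:
            sig_occurs[sig] = {
                p: s.config.assignment[p] is not None for p in pairs
            }

    n_pairs = len(pairs)
    signature_bf = {
        sig: bayes_factor(
            c, n, prior_probability(n_pairs, _signature_zero_count(sig), prior_mode)
        )
        for sig, c in counts.items()
    }
    top = top_model_set(signature_bf, bf_threshold)

    # qualitative full model: no transition fixed to zero, any partition
    full_count = sum(c for sig, c in counts.items() if _signature_zero_count(sig) == 0)
    full_prior = bell_number(n_pairs) / model_space_size(n_pairs)
    full_bf = bayes_factor(full_count, n, full_prior)

    sigs = sorted(counts)
    modal = [modal_root_state(by_sig_roots[sig], states) for sig in sigs]
    weights = [float(counts[sig]) for sig in sigs]
    occurrences = [sig_occurs[sig] for sig in sigs]
    anc_full = ancestral_mp(modal, states, weights)
    tr_full = transition_mp(occurrences, pairs, weights)

    # Final MPs cumulate over the top model set only, but keep the full
    # posterior sample size as denominator: a feature's "occurring" and
    # "not occurring" probabilities then rarely sum to 1, because mass on
    # models outside the top set supports neither verdict.
    if top:
        top_sigs = set(top)
        anc_top = {s: [0.0, 0.0] for s in states}
        tr_top = {p: [0.0, 0.0] for p in pairs}
        for sig, m, w, occ in zip(sigs, modal, weights, occurrences):
            if sig not in top_sigs:
                continue
            for s in states:
                share = w / len(m) if s in m else 0.0
                anc_top[s][1] += share
                anc_top[s][0] += w - share if s in m else w
            for p in pairs:
                tr_top[p][1 if occ[p] else 0] += w
        anc_top = {s: (v[0] / n, v[1] / n) for s, v in anc_top.items()}
        tr_top = {p: (v[0] / n, v[1] / n) for p, v in tr_top.items()}
    else:
        anc_top, tr_top = anc_full, tr_full

    avg_roots, avg_rates = average_probabilities(samples)
    return InferenceSummary(
        states=states,
        n_samples=n,
        signature_counts=dict(counts),
        signature_bf=signature_bf,
        top_set=top,
        bf_threshold=bf_threshold,
        full_model_bf=full_bf,
        ancestral_full=anc_full,
        ancestral_top=anc_top,
        transition_full=tr_full,
        transition_top=tr_top,
        avg_root_probs=avg_roots,
        avg_rates=avg_rates,
        prior_mode=prior_mode,
        name=name,
    )


def enumerate_configurations(
    pairs: Sequence[Pair] | int,
) -> Iterable[tuple[frozenset, tuple[frozenset, ...]]]:
    """Exhaustively generate all (zero set, partition) configurations.

    Oracle for :func:`model_space_size`; feasible for a handful of pairs.
    """
    if isinstance(pairs, int):
        items: list = list(range(pairs))
    else:
        items = list(pairs)

    def partitions(seq: list) -> Iterable[tuple[frozenset, ...]]:
        if not seq:
            yield ()
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + (block | {head},) + part[i + 1:]
            yield part + (frozenset({head}),)

    n = len(items)
    for mask in range(2 ** n):
        zero = frozenset(items[i] for i in range(n) if mask >> i & 1)
        free = [x for x in items if x not in zero]
        for part in partitions(free):
            yield zero, tuple(sorted(part, key=lambda b: sorted(map(str, b))))
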