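"""Trait containers and patch/whole-body coding rules.

A :class:`TraitColumn` holds, for one plumage patch, a non-empty set of
allowed states per taxon: a singleton for an unambiguous observation, the
full four-state set for missing/mottled data, and an intermediate set for
twigs that replace collapsed clades.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .states import (
    FULL_SET,
    STATE_ORDER,
    StateSet,
    break_tie,
    sort_states,
    state_set_label,
)

logger = logging.getLogger(__name__)


@dataclass
class TraitColumn:
    """Per-taxon state assignment for a single patch."""

    assignments: dict[str, StateSet]
    name: str = "trait"

    def __post_init__(self) -> None:
        for taxon, states in self.assignments.items():
            if not states:
                raise ValueError(f"empty state set for taxon {taxon!r}")
            bad = set(states) - set(STATE_ORDER)
            if bad:
                raise ValueError(f"unknown states {sorted(bad)} for {taxon!r}")
            self.assignments[taxon] = frozenset(states)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def __getitem__(self, taxon: str) -> StateSet:
        return self.assignments[taxon]

    def is_ambiguous(self, taxon: str) -> bool:
        return len(self.assignments[taxon]) > 1

    def subset(self, taxa: Iterable[str]) -> "TraitColumn":
        keep = set(taxa)
        return TraitColumn(
            {t: s for t, s in self.assignments.items() if t in keep},
            name=self.name,
        )

    def to_tsv(self) -> str:
        lines = ["taxon\tstate"]
        for taxon, states in self.assignments.items():
            lines.append(f"{taxon}\t{state_set_label(states)}")
        return "\n".join(lines) + "\n"


@dataclass
class PatchTable:
    """Taxon x patch grid of state sets (wide layout)."""

    columns: dict[str, TraitColumn]

    def __post_init__(self) -> None:
        taxa_sets = {frozenset(c.taxa) for c in self.columns.values()}
        if len(taxa_sets) > 1:
            raise ValueError("patch columns cover different taxon sets")

    @property
    def patches(self) -> tuple[str, ...]:
        return tuple(self.columns)

    @property
    def taxa(self) -> tuple[str, ...]:
        first = next(iter(self.columns.values()))
        return first.taxa

    def row(self, taxon: str) -> dict[str, StateSet]:
        return {p: c[taxon] for p, c in self.columns.items()}


def majority_state(
    observations: Sequence[Sequence[tuple[str, float]]],
) -> str:
    """Representative state from per-individual coverage observations.

    ``observations[i]`` lists ``(state, coverage_fraction)`` for individual
    ``i``; within each individual the state covering the largest fraction of
    feathers wins, and across individuals the modal per-individual state is
    taken.  Exact ties are broken deterministically by canonical state order
    with a logged warning.
    """
    if not observations:
        raise ValueError("no observations")
    per_individual: list[str] = []
    for obs in observations:
        if not obs:
            raise ValueError("individual with no scored patterns")
        total = sum(frac for _, frac in obs)
        if total > 1.0 + 1e-9:
            raise ValueError(f"coverage fractions sum to {total} > 1")
        best = max(frac for _, frac in obs)
        winners = [s for s, frac in obs if frac == best]
        per_individual.append(break_tie(winners))
    counts = Counter(per_individual)
    top = max(counts.values())
    modal = [s for s, c in counts.items() if c == top]
    return break_tie(modal)


@dataclass
class PatchStateSpace:
    """Observed-state summary for a patch, with an exclusion flag."""

    states: tuple[str, ...]
    drop: bool
    counts: dict[str, int] = field(default_factory=dict)


def patch_state_space(
    column: TraitColumn,
    min_taxa_per_state: int = 1,
    rare_state_threshold: int = 8,
) -> PatchStateSpace:
    """States observed unambiguously in enough taxa, plus a drop flag.

    A patch is flagged for exclusion when fewer than two states clear
    ``min_taxa_per_state``, or when exactly two states do but the rarer one
    is confined to fewer than ``rare_state_threshold`` taxa — the situation
    in which a single rare pattern in a derived clade carries the whole
    signal and the patch is better removed than modeled.
    """
    if min_taxa_per_state < 1:
        raise ValueError("min_taxa_per_state must be >= 1")
    counts: Counter[str] = Counter()
    for taxon in column.taxa:
        states = column[taxon]
        if len(states) == 1:
            counts[next(iter(states))] += 1
    space = tuple(s for s in STATE_ORDER if counts.get(s, 0) >= min_taxa_per_state)
    drop = len(space) < 2
    if len(space) == 2:
        rarer = min(counts[s] for s in space)
        if rarer < rare_state_threshold:
            drop = True
    return PatchStateSpace(states=space, drop=drop, counts=dict(counts))


def whole_body_recode(
    row: Mapping[str, StateSet],
    derived_order: Sequence[str],
) -> StateSet:
    """Collapse a species' per-patch states to its most recently evolved one.

    ``derived_order`` is a total order from ancestral to most derived (as
    inferred by the summary model of local evolution); among all states shown
    unambiguously in any patch, the latest in that order is representative.
    Fully ambiguous (mottled) patches are ignored; a species ambiguous in
    every patch is returned as the full set (missing for the global model).
    """
    order = tuple(derived_order)
    if sort_states(order) != tuple(sort_states(STATE_ORDER)) or len(order) != 4:
        raise ValueError(f"derived_order must be a total order over the 4 states, got {order}")
    present: set[str] = set()
    for states in row.values():
        if len(states) == 1:
            present |= set(states)
    if not present:
        return FULL_SET
    latest = max(present, key=order.index)
    return frozenset({latest})


def enumerate_order_variants(
    constraints: Iterable[tuple[str, str]],
) -> list[tuple[str, ...]]:
    """All total orders over the 4 states consistent with ``constraints``.

    ``constraints`` is a set of ``(earlier, later)`` pairs forming a DAG;
    linear extensions are enumerated by brute force over the 4! permutations
    (exact at this size) and returned in deterministic lexicographic order
    with respect to canonical state indices.
    """
    cons = [(a, b) for a, b in constraints]
    for a, b in cons:
        sort_states([a, b])  # validates state names
    # cycle check via simple DFS
    adj: dict[str, set[str]] = {s: set() for s in STATE_ORDER}
    for a, b in cons:
        adj[a].add(b)

    def reaches(src: str, dst: str, seen: set[str]) -> bool:
        if src == dst:
            return True
        seen.add(src)
        return any(reaches(n, dst, seen) for n in adj[src] if n not in seen)

    for a, b in cons:
        if reaches(b, a, set()):
            raise ValueError(f"cyclic constraints involving {a!r} and {b!r}")

    out: list[tuple[str, ...]] = []
    for perm in itertools.permutations(STATE_ORDER):
        pos = {s: i for i, s in enumerate(perm)}
        if all(pos[a] < pos[b] for a, b in cons):
            out.append(perm)
    out.sort(key=lambda perm: tuple(STATE_ORDER.index(s) for s in perm))
    return out
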