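"""Cross-patch summary models and the whole-body pipeline.

Per-patch marginal probabilities are reduced to verdicts (a transition
occurs, is absent, or is equivocal), aggregated into x/y counts across the
patches in which both states exist (equivocal patches contribute 0.5), and
the directed graph of occurring transitions yields the order in which
patterns first evolved — the order used to recode species to their most
recently evolved pattern for the single whole-body analysis.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Sequence

from .ctmc import Pair
from .inference import InferenceSummary
from .states import STATE_ORDER

logger = logging.getLogger(__name__)

OCCURS = "occurs"
ABSENT = "absent"
EQUIVOCAL = "equivocal"


@dataclass
class PatchVerdicts:
    """Per-pair verdicts for one patch, with its modeled state space."""

    patch: str
    states: tuple[str, ...]
    verdicts: dict[Pair, str]


def patch_verdicts(
    summary: InferenceSummary,
    tolerance: float = 0.0,
    collection: str = "top",
    patch: str | None = None,
) -> PatchVerdicts:
    """Classify each transition by its model-averaged marginal probabilities.

    A transition occurs when MP(occurring) exceeds MP(not occurring) by more
    than ``tolerance``; it is absent in the mirror case; exact (or
    within-tolerance) ties are equivocal.  Verdicts exist only for pairs
    inside the patch's modeled state space.
    """
    mps = summary.transition_top if collection == "top" else summary.transition_full
    verdicts: dict[Pair, str] = {}
    for pair, (mp_not, mp_occ) in mps.items():
        if mp_occ - mp_not > tolerance:
            verdicts[pair] = OCCURS
        elif mp_not - mp_occ > tolerance:
            verdicts[pair] = ABSENT
        else:
            verdicts[pair] = EQUIVOCAL
    return PatchVerdicts(
        patch=patch or summary.name, states=summary.states, verdicts=verdicts
    )


@dataclass
class SummaryCounts:
    """Cross-patch x/y tallies per ordered pair (halves from equivocal)."""

    numerators: dict[Pair, float]
    denominators: dict[Pair, int]

    def fraction_label(self, pair: Pair) -> str:
        num = self.numerators[pair]
        text = f"{num:g}"
        return f"{text}/{self.denominators[pair]}"


def aggregate_patches(per_patch: Sequence[PatchVerdicts]) -> SummaryCounts:
    """Combine patch verdicts into "occurs in x of y patches" counts.

    A patch is eligible for a pair only when both of the pair's states are
    in its modeled space; occurs adds 1, equivocal 0.5, absent 0.
    """
    if not per_patch:
        raise ValueError("no patch verdicts to aggregate")
    all_pairs = [(a, b) for a in STATE_ORDER for b in STATE_ORDER if a != b]
    numerators = {p: 0.0 for p in all_pairs}
    denominators = {p: 0 for p in all_pairs}
    for pv in per_patch:
        space = set(pv.states)
        for pair in all_pairs:
            if pair[0] in space and pair[1] in space:
                denominators[pair] += 1
                verdict = pv.verdicts.get(pair)
                if verdict == OCCURS:
                    numerators[pair] += 1.0
                elif verdict == EQUIVOCAL:
                    numerators[pair] += 0.5
    return SummaryCounts(numerators=numerators, denominators=denominators)


def first_evolved_order(
    occurring_edges: Sequence[Pair],
    ancestral_state: str,
) -> list[set[str]]:
    """Breadth-first layering of states by first reachability from the ancestor.

    Returns depth layers as a partial order: states first reached at the
    same depth are tied (e.g. both scales and bars directly reachable from
    an absence of patterning).  States unreachable through any occurring
    transition are flagged and placed in a final layer.
    """
    adjacency: dict[str, set[str]] = {}
    for a, b in occurring_edges:
        adjacency.setdefault(a, set()).add(b)
    depth = {ancestral_state: 0}
    queue = deque([ancestral_state])
    while queue:
        node = queue.popleft()
        for nxt in sorted(adjacency.get(node, ())):
            if nxt not in depth:
                depth[nxt] = depth[node] + 1
                queue.append(nxt)
    layers: list[set[str]] = []
    for d in range(max(depth.values()) + 1):
        layers.append({s for s, dd in depth.items() if dd == d})
    unreachable = {s for s in STATE_ORDER if s not in depth}
    if unreachable:
        logger.warning(
            "states %s unreachable from %r via occurring transitions; placed last",
            sorted(unreachable), ancestral_state,
        )
        layers.append(unreachable)
    return layers


def occurring_edges_from_counts(
    counts: SummaryCounts, min_fraction: float = 0.5
) -> list[Pair]:
    """Pairs occurring in more than ``min_fraction`` of eligible patches."""
    out = []
    for pair, denom in counts.denominators.items():
        if denom > 0 and counts.numerators[pair] / denom > min_fraction:
            out.append(pair)
    return out


def partial_order_constraints(layers: Sequence[set[str]]) -> list[tuple[str, str]]:
    """Pairwise (earlier, later) constraints implied by depth layers."""
    constraints = []
    for i, layer in enumerate(layers):
        for later_layer in layers[i + 1:]:
            for a in sorted(layer):
                for b in sorted(later_layer):
                    constraints.append((a, b))
    return constraints


def to_dot(
    counts_or_mps: SummaryCounts | InferenceSummary,
    title: str = "pattern evolution",
) -> str:
    """Graphviz DOT digraph styled like the published figures.

    Black edges: the transition probably occurs; grey: probably not; edge
    labels carry the x/y patch counts (summary) or MP pairs (single model);
    width scales with the mean rate when available.
    """
    lines = [f'digraph "{title}" {{', "  rankdir=LR;"]
    for s in STATE_ORDER:
        lines.append(f'  "{s}";')
    if isinstance(counts_or_mps, SummaryCounts):
        for pair, denom in counts_or_mps.denominators.items():
            if denom == 0:
                continue
            frac = counts_or_mps.numerators[pair] / denom
            color = "black" if frac > 0.5 else "grey"
            label = counts_or_mps.fraction_label(pair)
            lines.append(
                f'  "{pair[0]}" -> "{pair[1]}" [color={color}, label="{label}"];'
            )
    else:
        summary = counts_or_mps
        max_rate = max(summary.avg_rates.values(), default=1.0) or 1.0
        for pair, (mp_not, mp_occ) in summary.transition_top.items():
            color = "black" if mp_occ > mp_not else "grey"
            width = 1.0 + 3.0 * summary.avg_rates[pair] / max_rate
            lines.append(
                f'  "{pair[0]}" -> "{pair[1]}" [color={color}, '
                f'label="{mp_not:.2f}; {mp_occ:.2f}", penwidth={width:.2f}];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def whole_body_pipeline_orders(
    per_patch: Sequence[PatchVerdicts],
    ancestral_state: str,
) -> list[tuple[str, ...]]:
    """Candidate derived orders for whole-body recoding.

    Summary counts → occurring edges → BFS layering → all linear extensions
    of the resulting partial order (ties at equal depth produce the
    alternative trajectories that are each analyzed globally).
    """
    from .traits import enumerate_order_variants

    counts = aggregate_patches(per_patch)
    edges = occurring_edges_from_counts(counts)
    layers = first_evolved_order(edges, ancestral_state)
    constraints = partial_order_constraints(layers)
    return enumerate_order_variants(constraints)
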