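"""Pattern state space and raw-label normalization.

The analysis models within-feather patterning as a four-state discrete
character: an absence of patterning, scales, bars and spots.  Missing or
uninterpretable observations (mottled plumage) are represented as the full
ambiguity set over the four states, never as a fifth state, so they
contribute flat partial likelihoods rather than extra rate parameters.
"""

from __future__ import annotations

import logging
from typing import FrozenSet, Iterable, Sequence

logger = logging.getLogger(__name__)

ABSENCE = "absence"
SCALES = "scales"
BARS = "bars"
SPOTS = "spots"

#: Canonical state order; also the deterministic tie-break order.
STATE_ORDER: tuple[str, ...] = (ABSENCE, SCALES, BARS, SPOTS)

#: Full ambiguity set ("unknown"/"mottled").
FULL_SET: FrozenSet[str] = frozenset(STATE_ORDER)

StateSet = FrozenSet[str]

#: Raw scoring vocabulary -> analysis state set.  Chevrons are an angular
#: variant of barring (borders do not meet to enclose a pigment patch) and
#: are coded as bars; longitudinal stripes are angular scales with a central
#: pigment patch and are coded as scales; mottled plumage has no regular
#: motif and is coded as unknown (full ambiguity).
VOCABULARY: dict[str, StateSet] = {
    ABSENCE: frozenset({ABSENCE}),
    SCALES: frozenset({SCALES}),
    BARS: frozenset({BARS}),
    SPOTS: frozenset({SPOTS}),
    "chevron": frozenset({BARS}),
    "longitudinal_stripe": frozenset({SCALES}),
    "mottled": FULL_SET,
    "unknown": FULL_SET,
    "?": FULL_SET,
}

#: The seven body patches scored per species.
PATCHES: tuple[str, ...] = (
    "nape", "wing", "rump", "tail", "breast", "flanks", "vent",
)


class UnknownLabelError(ValueError):
    """Raised for a raw score token outside the documented vocabulary."""


def normalize_label(raw: str) -> StateSet:
    """Map a raw scoring token to its analysis state set.

    Multi-state tokens use ``|`` as separator (e.g. ``"bars|spots"`` for a
    twig whose collapsed members had both patterns).
    """
    token = raw.strip().lower()
    if "|" in token:
        parts = [p for p in token.split("|") if p]
        if not parts:
            raise UnknownLabelError(f"empty multi-state token {raw!r}")
        out: set[str] = set()
        for part in parts:
            out |= normalize_label(part)
        return frozenset(out)
    if token not in VOCABULARY:
        raise UnknownLabelError(
            f"unrecognized state label {raw!r}; vocabulary: "
            + ", ".join(sorted(VOCABULARY))
        )
    return VOCABULARY[token]


def state_set_label(states: StateSet) -> str:
    """Canonical text form of a state set (inverse of :func:`normalize_label`)."""
    if not states:
        raise ValueError("empty state set")
    if states == FULL_SET:
        return "unknown"
    ordered = [s for s in STATE_ORDER if s in states]
    return "|".join(ordered)


def order_index(state: str) -> int:
    return STATE_ORDER.index(state)


def sort_states(states: Iterable[str]) -> tuple[str, ...]:
    """States sorted in canonical order."""
    out = tuple(s for s in STATE_ORDER if s in set(states))
    missing = set(states) - set(out)
    if missing:
        raise ValueError(f"unknown states: {sorted(missing)}")
    return out


def break_tie(candidates: Sequence[str]) -> str:
    """Deterministic tie-break: earliest state in :data:`STATE_ORDER`."""
    ordered = sort_states(candidates)
    if len(set(candidates)) > 1:
        logger.warning(
            "tie between states %s broken to %r by canonical order",
            sorted(set(candidates)), ordered[0],
        )
    return ordered[0]
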