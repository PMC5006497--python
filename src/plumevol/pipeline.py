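"""End-to-end orchestration: per-patch runs, summary model, whole-body runs."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .inference import InferenceSummary, summarize
from .phylo import Phylogeny, reconcile
from .rjmcmc import ChainConfig, MultiChainResult, run_chains
from .summary import PatchVerdicts, patch_verdicts
from .traits import PatchTable, TraitColumn, patch_state_space, whole_body_recode

logger = logging.getLogger(__name__)


@dataclass
class PatchAnalysis:
    patch: str
    summary: InferenceSummary
    chains: MultiChainResult
    states: tuple[str, ...]
    verdicts: PatchVerdicts


def analyze_patch(
    tree: Phylogeny,
    column: TraitColumn,
    chain_config: ChainConfig,
    bf_threshold: float = 2.0,
    min_taxa_per_state: int = 1,
    rare_state_threshold: int = 8,
    on_missing_taxon: str = "prune",
) -> PatchAnalysis | None:
    """Run one patch end-to-end; ``None`` when the patch is excluded.

    The modeled state space shrinks to the states actually observed in the
    patch (a three-state patch has 6 ordered pairs rather than 12); patches
    flagged by the rarity rule are skipped.
    """
    column = reconcile(tree, column, on_missing_taxon=on_missing_taxon)
    space = patch_state_space(
        column, min_taxa_per_state=min_taxa_per_state,
        rare_state_threshold=rare_state_threshold,
    )
    if space.drop:
        logger.warning("patch %r excluded (observed states: %s)",
                       column.name, space.counts)
        return None
    states = space.states
    result = run_chains(tree, column, chain_config, states=states)
    summary = summarize(
        result.pooled, bf_threshold=bf_threshold, name=column.name
    )
    verdicts = patch_verdicts(summary, patch=column.name)
    return PatchAnalysis(
        patch=column.name, summary=summary, chains=result,
        states=states, verdicts=verdicts,
    )


def recode_whole_body(
    table: PatchTable, derived_order: tuple[str, ...]
) -> TraitColumn:
    """Single whole-body column: each species' most recently evolved pattern."""
    assignments = {
        taxon: whole_body_recode(table.row(taxon), derived_order)
        for taxon in table.taxa
    }
    return TraitColumn(assignments, name="whole_body")
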