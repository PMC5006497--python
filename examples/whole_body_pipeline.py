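"""From per-patch verdicts to the whole-body recoding.

Aggregates transition verdicts across patches into "occurs in x of y
patches" counts (equivocal patches contribute 0.5), derives the order in
which patterns first evolved, enumerates the total orders consistent with
it, and recodes multi-patterned species to their most recently evolved
pattern — the single character used in a whole-body analysis.
"""

from plumevol import aggregate_patches, whole_body_recode
from plumevol.states import ABSENCE, BARS, SCALES, SPOTS, STATE_ORDER
from plumevol.summary import (
    ABSENT,
    EQUIVOCAL,
    OCCURS,
    PatchVerdicts,
    first_evolved_order,
    occurring_edges_from_counts,
    partial_order_constraints,
)
from plumevol.traits import enumerate_order_variants

# verdicts for five four-state patches (as produced by patch_verdicts on
# each patch's RJMCMC summary); one patch is equivocal about absence->spots
base = {
    (ABSENCE, BARS): OCCURS, (BARS, SCALES): OCCURS, (SCALES, BARS): OCCURS,
    (SCALES, SPOTS): OCCURS, (ABSENCE, SPOTS): ABSENT, (SPOTS, ABSENCE): ABSENT,
}
patches = []
for i in range(5):
    verdicts = dict(base)
    if i == 0:
        verdicts[(ABSENCE, SPOTS)] = EQUIVOCAL
    patches.append(PatchVerdicts(f"patch{i}", STATE_ORDER, verdicts))

counts = aggregate_patches(patches)
print("cross-patch summary counts (occurs in x of y eligible patches):")
for pair in base:
    print(f"  {pair[0]:>8} -> {pair[1]:<8} {counts.fraction_label(pair)}")
print("the 0.5 comes from the single equivocal patch model.")

edges = occurring_edges_from_counts(counts)
layers = first_evolved_order(edges, ABSENCE)
print("\norder of first evolution (breadth-first layers):", layers)

orders = enumerate_order_variants(partial_order_constraints(layers))
print("total orders consistent with the layering:", orders)

order = orders[0]
species = {"flanks": frozenset({BARS}), "breast": frozenset({SPOTS}),
           "vent": frozenset({ABSENCE})}
recoded = whole_body_recode(species, order)
print(f"\nspecies with bars + spots + unpatterned patches recodes to "
      f"{set(recoded)} — its most recently evolved pattern.")
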