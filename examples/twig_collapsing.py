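"""Collapse poorly supported branches into twigs with union state coding.

Clades whose subtending branch has Bayesian support <= 0.95 are replaced by
a single "twig" terminal carrying every pattern state of its member
species, converting topological uncertainty into trait ambiguity.
"""

from plumevol import (
    Phylogeny,
    TraitColumn,
    apply_twig_coding,
    collapse_low_support,
)
from plumevol.states import ABSENCE, BARS, SPOTS

tree = Phylogeny.from_string(
    "(((sp1:1,sp2:1)0.99:1,(sp3:1,(sp4:1,sp5:1)0.97:0.5)0.80:1)0.99:1,sp6:3);"
)
traits = TraitColumn(
    {
        "sp1": {ABSENCE}, "sp2": {ABSENCE}, "sp3": {SPOTS},
        "sp4": {BARS}, "sp5": {BARS}, "sp6": {ABSENCE},
    }
)

print("before:", tree.n_tips, "tips; supports:", tree.supports())
collapsed, twigs = collapse_low_support(tree, threshold=0.95)
print("after: ", collapsed.n_tips, "tips;", len(twigs), "twig(s)")
for label, members in twigs.members.items():
    print(f"  {label}: replaces {sorted(members)}")

recoded = apply_twig_coding(traits, twigs)
for label in twigs.members:
    states = "|".join(sorted(recoded[label]))
    print(f"  {label} coded as {{{states}}} — the union of its members' states")
print("\ncollapsed newick:", collapsed.to_newick().strip())
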