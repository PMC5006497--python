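"""Rate matrices, transition probabilities and pruning likelihoods.

Builds a sparse four-state rate configuration on a toy five-species tree,
evaluates the probability of a trait column (including one mottled species
scored as fully ambiguous), and reads off the posterior state probabilities
at the root.
"""

import math

import numpy as np

from plumevol import (
    Phylogeny,
    RateConfiguration,
    TraitColumn,
    build_rate_matrix,
    log_likelihood,
    root_marginals,
    transition_matrix,
)
from plumevol.states import ABSENCE, BARS, SCALES, SPOTS, STATE_ORDER

tree = Phylogeny.from_string(
    "(((sp1:1,sp2:1):1,(sp3:1.5,sp4:0.5):1):1,sp5:3);"
)
traits = TraitColumn(
    {
        "sp1": {ABSENCE},
        "sp2": {BARS},
        "sp3": {BARS},
        "sp4": {SCALES},
        "sp5": set(STATE_ORDER),  # mottled: constrains nothing
    }
)

config = RateConfiguration.from_rates(
    STATE_ORDER,
    {(ABSENCE, BARS): 0.3, (BARS, SCALES): 0.2, (SCALES, BARS): 0.2,
     (SCALES, SPOTS): 0.1},
)
Q = build_rate_matrix(config)
print("rate matrix Q (rows sum to zero):")
print(np.round(Q, 3))

P = transition_matrix(Q, 1.0)
print("\ntransition probabilities over one unit of branch length, P = exp(Q):")
print(np.round(P, 3))
print("each row is a probability distribution over the end state.")

ll = log_likelihood(tree, traits, Q)
print(f"\npruning log-likelihood of the trait column: {ll:.4f}")
print(f"(likelihood {math.exp(ll):.3e}; the ambiguous tip sums over all states)")

roots = root_marginals(tree, traits, Q)
print("\nposterior root-state probabilities under a uniform root prior:")
for state, p in zip(STATE_ORDER, roots):
    print(f"  {state:>8}: {p:.3f}")
print("the most probable ancestral state given tips, topology and rates.")
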