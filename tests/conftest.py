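import math

import pytest

from plumevol import Phylogeny, TraitColumn
from plumevol.states import ABSENCE, BARS, SCALES, SPOTS


@pytest.fixture
def two_state():
    """Two-state space used for closed-form checks."""
    return (ABSENCE, SCALES)


@pytest.fixture
def cherry_tree():
    """Two tips joined at the root, branch lengths ln(2)/2."""
    t = math.log(2.0) / 2.0
    return Phylogeny.from_string(f"(A:{t},B:{t});")


@pytest.fixture
def six_tip_tree():
    """Six tips with one poorly supported three-tip clade (support 0.80)."""
    return Phylogeny.from_string(
        "(((A:1,B:1)0.99:1,(C:1,(D:1,E:1)0.97:0.5)0.80:1)0.99:1,F:3);"
    )


@pytest.fixture
def balanced_tree():
    return Phylogeny.from_string("((A:1,B:1)0.98:1,(C:1,D:1)0.99:1);")


@pytest.fixture
def four_state_column():
    return TraitColumn(
        {
            "A": {ABSENCE},
            "B": {BARS},
            "C": {SCALES},
            "D": {SPOTS},
        }
    )
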