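"""Published summary data used as worked-example inputs.

The per-patch pattern-frequency summary for the two most richly patterned
game-bird clades — waterfowl (Anseriformes, 118 sampled species) and
gamebirds (Galliformes, 170 sampled species) — tabulates how many sampled
species show each pattern state (or mottled/unknown plumage) in each of the
seven body patches.  Row sums therefore recover each clade's sampled
species total, a cheap integrity check on the transcription.
"""

from __future__ import annotations

import io

import pandas as pd

_PATTERN_FREQUENCIES_TSV = """\
clade	patch	absence	scales	bars	spots	mottled
Anseriformes	nape	78	16	19	3	2
Anseriformes	wing	105	5	5	1	2
Anseriformes	rump	100	12	4	0	2
Anseriformes	tail	109	7	0	0	2
Anseriformes	breast	74	14	12	13	5
Anseriformes	flanks	65	11	34	5	3
Anseriformes	vent	86	9	14	4	5
Galliformes	nape	75	18	29	10	38
Galliformes	wing	81	14	13	9	53
Galliformes	rump	83	11	25	8	43
Galliformes	tail	93	0	24	8	45
Galliformes	breast	105	16	17	13	19
Galliformes	flanks	79	21	29	14	27
Galliformes	vent	139	6	11	4	10
"""

STATE_COLUMNS = ("absence", "scales", "bars", "spots", "mottled")


def pattern_frequency_table() -> pd.DataFrame:
    """Per-clade, per-patch species counts by pattern state."""
    return pd.read_csv(io.StringIO(_PATTERN_FREQUENCIES_TSV), sep="\t")


def clade_species_totals() -> dict[str, int]:
    """Sampled species per clade, recovered from the frequency rows.

    Every patch row of a clade scores the same species sample, so all its
    row sums must agree; disagreement would mean a transcription error.
    """
    df = pattern_frequency_table()
    sums = df[list(STATE_COLUMNS)].sum(axis=1)
    out: dict[str, int] = {}
    for clade in df["clade"].unique():
        values = set(sums[df["clade"] == clade])
        if len(values) != 1:
            raise ValueError(f"inconsistent row sums for {clade}: {sorted(values)}")
        out[clade] = int(values.pop())
    return out
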