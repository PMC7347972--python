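"""Published general characteristics of the eight Neotropical
*Bulbophyllum* plastomes (GenBank MN604054-MN604059, MN737573,
MN580547), as reported with their deposition.

These are inputs for the length-relationship statistics (SSC range vs
total range, SSC ~ total regression) when the full records themselves
are not at hand.  Lengths in bp; GC as percent.
"""

from __future__ import annotations

import pandas as pd

BULBOPHYLLUM_PLASTOMES = [
    # species, accession, total, LSC, SSC, IR, GC%
    ("B_mentosum", "MN604056", 150217, 83642, 13895, 26340, 36.7),
    ("B_epiphytum", "MN737573", 147546, 82354, 13497, 25847, 36.7),
    ("B_plumosum", "MN580547", 146401, 83260, 11089, 26026, 36.6),
    ("B_weddellii", "MN604059", 151355, 83450, 16049, 25928, 36.6),
    ("B_exaltatum", "MN604054", 150410, 83335, 15380, 25847, 36.8),
    ("B_granulosum", "MN604055", 151112, 84492, 15690, 25465, 36.7),
    ("B_regnellii", "MN604057", 151493, 84868, 15541, 25542, 36.7),
    ("B_steyermarkii", "MN604058", 146720, 83488, 11321, 25955, 36.7),
]


def reference_table() -> pd.DataFrame:
    df = pd.DataFrame(
        BULBOPHYLLUM_PLASTOMES,
        columns=["species", "accession", "total", "lsc", "ssc", "ir", "gc_percent"],
    )
    df["reconstructed_total"] = df.lsc + df.ssc + 2 * df.ir
    return df
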