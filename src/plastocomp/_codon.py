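"""Shared genetic-code tables and codon indexing.

Standard genetic code throughout (plastid CDSs are translated with the
standard code here; alternative initiation codons are handled as audit
exceptions, not as a different code).
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "TCAG"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> one-letter amino acid, '*' for stop (standard code)
GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(NUCLEOTIDES, repeat=3)):
    GENETIC_CODE[_a + _b + _c] = _AA[_i]

ALL_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
STOP_CODONS: frozenset[str] = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid -> tuple of synonymous codons (sense only)
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMOUS.setdefault(GENETIC_CODE[_c], ())
for _c in SENSE_CODONS:
    _aa = GENETIC_CODE[_c]
    SYNONYMOUS[_aa] = SYNONYMOUS[_aa] + (_c,)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; codons with N become 'X'."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(GENETIC_CODE.get(seq[i : i + 3], "X"))
    return "".join(out)
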