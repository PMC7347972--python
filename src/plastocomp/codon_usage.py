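"""Codon usage counts, RSCU and start-codon audits.

RSCU(c) = n_c * k_aa / sum of counts over the codons synonymous with c,
where k_aa is the family size under the standard genetic code.  Values
above 1 mark codons used more often than expected under uniform
synonymous usage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._codon import ALL_CODONS, GENETIC_CODE, SENSE_CODONS, STOP_CODONS, SYNONYMOUS
from .genome_io import PlastomeRecord, extract_feature_sequence


class FrameError(ValueError):
    """CDS length not divisible by 3."""


@dataclass
class CodonUsageTable:
    """Codon counts and RSCU for one genome (or pooled CDS set)."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: dict[str, float | None] = field(default_factory=dict)
    internal_stops: int = 0
    skipped_ambiguous: int = 0

    @property
    def total_sense(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def amino_acid_totals(self) -> dict[str, int]:
        out: Counter = Counter()
        for c in SENSE_CODONS:
            out[GENETIC_CODE[c]] += self.counts[c]
        return dict(out)

    def frequencies(self) -> dict[str, float]:
        tot = self.total
        return {c: (self.counts[c] / tot if tot else 0.0) for c in ALL_CODONS}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies()
        rows = [
            {
                "codon": c,
                "amino_acid": GENETIC_CODE[c],
                "count": self.counts[c],
                "frequency": freqs[c],
                "rscu": self.rscu.get(c),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def count_codons(cds_sequences: list[str], names: list[str] | None = None) -> CodonUsageTable:
    """Count codons over in-frame CDS sequences.

    Codons containing N are skipped; internal stop codons are counted
    but flagged; each sequence must be a multiple of 3 long.
    """
    table = CodonUsageTable()
    for idx, seq in enumerate(cds_sequences):
        seq = seq.upper()
        if len(seq) % 3:
            name = names[idx] if names else f"#{idx}"
            raise FrameError(f"CDS {name}: length {len(seq)} not divisible by 3")
        ncod = len(seq) // 3
        for i in range(ncod):
            codon = seq[3 * i : 3 * i + 3]
            if "N" in codon:
                table.skipped_ambiguous += 1
                continue
            table.counts[codon] += 1
            if codon in STOP_CODONS and i < ncod - 1:
                table.internal_stops += 1
    return table


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill the RSCU column; terminal/any stop codons are excluded.

    An unobserved amino-acid family gives RSCU None (0/0 undefined).
    """
    for aa, codons in SYNONYMOUS.items():
        fam_total = sum(table.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            table.rscu[c] = (table.counts[c] * k / fam_total) if fam_total else None
    for c in STOP_CODONS:
        table.rscu[c] = None
    return table


def genome_codon_usage(record: PlastomeRecord) -> CodonUsageTable:
    """Pooled codon usage over all intact (non-pseudogene) CDSs."""
    seqs, names = [], []
    for f in record.features:
        if f.kind != "CDS":
            continue
        seq = extract_feature_sequence(record, f)
        seq = seq[: len(seq) - len(seq) % 3]
        seqs.append(seq)
        names.append(f.name)
    return rscu(count_codons(seqs, names))


def start_codon_audit(records: list[PlastomeRecord]) -> list[tuple[str, str, str]]:
    """(gene, genome, start codon) for every CDS not starting with ATG."""
    out = []
    for rec in records:
        for f in rec.features:
            if f.kind != "CDS":
                continue
            seq = extract_feature_sequence(rec, f)
            if len(seq) >= 3 and seq[:3] != "ATG":
                out.append((f.name, rec.id, seq[:3]))
    return out


def usage_matrix(tables: dict[str, CodonUsageTable]) -> pd.DataFrame:
    """Genomes x codons RSCU matrix (heatmap-ready)."""
    return pd.DataFrame(
        {gid: {c: t.rscu.get(c) for c in SENSE_CODONS} for gid, t in tables.items()}
    ).T
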