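"""Codon usage and RSCU of one synthetic plastome.

Pools all intact CDSs of a genome, prints the most- and least-used
codons by RSCU, and audits non-ATG initiation codons.
"""

from plastocomp import simulate_study, start_codon_audit
from plastocomp.codon_usage import genome_codon_usage

_, records, _ = simulate_study(seed=1)
rec = records[0]
table = genome_codon_usage(rec)
df = table.to_frame().dropna(subset=["rscu"])

print(f"{rec.id}: {table.total_sense} sense codons in intact CDSs")
print("\nmost over-used codons (RSCU > 1 = used more than expected):")
print(df.nlargest(5, "rscu")[["codon", "amino_acid", "count", "rscu"]].to_string(index=False))
print("\nmost avoided codons:")
print(df.nsmallest(5, "rscu")[["codon", "amino_acid", "count", "rscu"]].to_string(index=False))

freqs = table.frequencies()
top = max(freqs, key=freqs.get)
print(f"\nmost frequent codon overall: {top} ({100 * freqs[top]:.2f}%)")
print("A/T-ending codons dominate, the usual plastid AT bias.")

audit = start_codon_audit(records)
print(f"\nnon-ATG start codons across the clade: {audit[:5]}")
print("(point mutations in starts flag putative pseudogenization or RNA editing)")
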