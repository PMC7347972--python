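"""Hypervariable-marker screen on the true simulated alignment.

Segments the alignment by the reference genome's CDS/intron/IGS map,
computes Eta/indel/PIS/SV statistics, pools per-class rates, and ranks
the ten most-variable regions.
"""

from plastocomp import (
    rank_segments,
    rate_table,
    region_class_map,
    segment_alignment,
    simulate_study,
    sv_at_correlation,
)
from plastocomp.variability import segments_frame

_, records, truth = simulate_study(seed=1)
aln = truth.alignment(include_ancestor=False)
ref = records[0]
segs = segment_alignment(aln, region_class_map(ref), ref.id, min_len=150)

print(f"{len(segs)} segments >= 150 bp (reference {ref.id})")
print("\nper-class rates (counts per 100 bp):")
print(rate_table(segs).rounded())

print("\ntop 10 markers by sequence variability:")
top = rank_segments(segs, 10)
print(segments_frame(top)[["name", "class", "ref_length", "mutations",
                           "indels", "pis", "sv"]].to_string(index=False))

r, p = sv_at_correlation(segs)
print(f"\nSV ~ AT-content Pearson r = {r:.2f} (p = {p:.2g})")
print("IGS segments dominate the ranking: non-coding sequence evolves")
print("fastest, so these spacers are the best phylogenetic markers.")
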