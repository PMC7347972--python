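"""Dispersed repeats, microsatellites and polymorphic SSR groups.

Scans one genome for long repeat pairs and SSRs, classifies them by
quadripartite region and CDS/intron/IGS class, then groups SSR loci
across the clade and checks primer constraints for a candidate pair.
"""

from plastocomp import (
    check_primer_constraints,
    classify_hits,
    detect_inverted_repeat,
    find_long_repeats,
    polymorphic_ssrs,
    region_class_map,
    scan_ssrs,
    simulate_study,
)

_, records, _ = simulate_study(seed=1)
rec = records[0]
part = detect_inverted_repeat(rec, min_len=2000)
rmap = region_class_map(rec)

hits = find_long_repeats(rec.sequence)  # >= 30 bp, <= 3 mismatches
hits, hit_summary = classify_hits(hits, part, rmap)
print(f"{rec.id}: {len(hits)} long repeat pairs")
for h in hits[:5]:
    print(f"  {h.klass:12s} {h.length} bp, {h.mismatches} mismatches"
          f"  {h.pos1}->{h.pos2}  ({h.region}, {h.region_class})")

loci = scan_ssrs(rec.sequence)  # thresholds 10/5/3/3/3/3
loci, ssr_summary = classify_hits(loci, part, rmap)
print(f"\n{len(loci)} SSR loci; counts by (region, class): {ssr_summary}")

groups = polymorphic_ssrs(
    {r.id: (r.sequence, scan_ssrs(r.sequence)) for r in records}
)
print(f"\npolymorphic SSR groups (>= 4 species, >= 2 repeat counts): {len(groups)}")
for g in groups[:3]:
    print(f"  motif {g.motif}: counts {g.counts}")
print("these are the loci worth developing as population-genetic markers.")

rep = check_primer_constraints(
    "ATGCATGCATGCATGCATGC", "GCATGCATGCATGCATGCAT", product_length=320
)
print(f"\nprimer-pair constraint check: {rep.passed} -> {'PASS' if rep.ok else 'FAIL'}")
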