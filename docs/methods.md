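# Methods

This note documents the models, statistics and design choices behind
`plastocomp`: a comparative analysis toolkit for plastid genomes built
around five capabilities — quadripartite structure and junction
analysis, codon usage (RSCU), dispersed-repeat and microsatellite
discovery, hypervariable-marker ranking, and site-level
positive-selection scanning — plus a synthetic plastome evolver that
makes every stage verifiable without external data.

## Quadripartite structure and junctions

A plastome is decomposed into LSC / IRb / SSC / IRa by locating the
maximal pair of intervals where one copy matches the reverse complement
of the other within a mismatch fraction.  Detection is seed-and-extend:
exact 25-mer matches between the sequence and its complement nominate
anti-diagonals; the candidate with the strongest seed support is
extended outward while the running mismatch fraction stays within
`max_mismatch_frac` (default 0.01, minimum IR length 10 kb on real-size
plastomes; the pipeline scales the minimum down for small synthetic
genomes).  The genome is searched in doubled form, so an IR spanning
the linearization origin is found and the classification of the IR/SSC
junction type is invariant to genome rotation.  Ties between
equally long candidates break to the leftmost first-copy start.  With
`max_mismatch_frac = 0` the extension stops at the first mismatch, so
planted IR boundaries are recovered exactly up to chance-matching flank
bases (at most ~1 bp in expectation, bounded in tests by guard bases).

Junctions are reported in the convention LSC–IRb–SSC–IRA around the
circle: J_LB, J_SB, J_SA, J_LA.  For each junction the overlapping
feature (or the nearest one within 1 kb) is reported with a signed
overlap: positive bp of the feature inside the IR, negative distance
when the feature stops short of the junction.  The IR/SSC junction type
follows the ndhF state: type 1 (ndhF present, wholly in the SSC),
type 2 (ndhF spans J_SB), type 3 (ndhF lost; the IR faces ycf1).

The ndh audit classifies each of the 11 ndh genes per genome as
*intact* (annotated CDS, ATG/GTG start, no internal stop, length at
least 90% of a reference length), *truncated* (present but failing a
check) or *lost* (no feature).  Length relationships use ordinary least
squares (SSC length vs total length; r², F(1, n−2)) and a Pearson
correlation between the summed ndh sequence residing in the SSC and SSC
length.  The choice of "summed residual ndh length in the SSC" as the
correlate is a design decision; the relationship it summarizes (ndh
loss drives SSC contraction, which drives total-length variation) is
what the statistic is meant to capture.  The regression report includes
both r² and F because a reader may need either; they are tied by
F = r²(n−2)/(1−r²).

## Codon usage

Codon counts pool all intact (non-pseudogene) CDSs of a genome, reading
each CDS in frame after `codon_start` trimming; codons containing N are
skipped and counted as skipped, internal stops are counted and flagged.
RSCU uses the standard genetic code:

    RSCU(c) = n_c * k_aa / sum over synonymous codons of n,

where `k_aa` is the synonymous family size.  Stop codons carry no RSCU;
an unobserved family reports RSCU as missing rather than 0/0.
Alternative initiation codons (GTG, ACG) are reported by the
start-codon audit but do not affect counting: they are putative
RNA-editing or pseudogenization signals, not different amino acids.

## Dispersed repeats and SSRs

Long repeats follow REPuter's three classes: forward (substring vs
substring), reverse (vs reversed substring, no complement) and
palindromic (vs reverse-complemented substring).  A hit is a pair of
equal-length copies with Hamming distance ≤ 3 and length ≥ 30 bp
(defaults), *maximal*: any extension either exceeds the mismatch budget
or leaves the sequence.  Every qualifying window must contain an exact
run of at least ⌈(30−3)/4⌉ = 7 bp (pigeonhole), so exact 7-mer seed
matches are a complete seed set; each seed is extended to every maximal
window containing it and duplicates are removed.  A per-diagonal
exhaustive enumeration with the same maximality rule serves as the
independent oracle in tests; the two agree exactly on all tested
inputs.  Reverse/palindromic pairs are enumerated once per unordered
pair along anti-diagonals, which keeps the two copies non-overlapping
by construction.

SSRs are maximal perfect tandem runs of a primitive 1–6 bp motif with
per-unit minimum repeat counts 10/5/3/3/3/3 (mono- to hexanucleotide).
Reporting a run only at its primitive unit makes a poly-A run a single
mononucleotide locus, never (AA)n; motifs are canonicalized to the
lexicographically minimal rotation over both strands, making total
counts invariant to reverse complementation.  Compound SSRs are not
merged; each simple run counts once.

Cross-species SSR homology is flank-based: loci group when canonical
motifs match and either flanking 20-mer matches with ≤ 2 mismatches; a
group is "polymorphic" when present in ≥ 4 species (configurable) with
at least two distinct repeat counts — presence alone is not enough.
Primer-pair constraint validation checks product length 100–500 bp,
primer length 18–27, GC 40–60%, and ΔTm ≤ 1 °C with the simple
salt-free formula Tm = 64.9 + 41(GC−16.4)/len, declared in output; any
fixed formula satisfies the ΔTm rule reproducibly.

## Hypervariable-marker statistics

From a master alignment plus the per-base CDS/intron/IGS map of a
designated reference genome, contiguous same-class reference runs are
projected to alignment columns; segments are kept when the ungapped
reference length is ≥ 150 bp and no sequence is almost entirely gap
inside the segment (> 90% gap marks a rearrangement or an absent
region — the operational form of "flanked by the same region in every
genome").  Per segment:

- **mutations (Eta)** — over gap-free columns, Σ (distinct states − 1);
- **indel events** — simple indel coding: one event per distinct gap
  span (start, end), shared-endpoint spans count once, nested or
  staggered spans count separately;
- **conserved sites** — gap-free monomorphic columns;
- **PIS** — gap-free columns with ≥ 2 states each in ≥ 2 sequences;
- **SV** = 100 (Eta + indels) / (conserved + Eta + indels), missing
  when the denominator is zero.

Gap-containing columns are excluded from Eta/conserved/PIS and handled
solely through indel events.  Rates pool counts per class and divide by
pooled ungapped reference length per 100 bp; values are stored at full
precision and rounded half-away-from-zero only at presentation.
Ranking is by SV descending with ties broken by PIS, then segment
length, then name, so the top-k list is deterministic.

## Site-selection scan (M0 / M8a / M8)

Codon substitution follows GY94: rate i→j is zero unless the codons
differ at one position, otherwise π_j·κ^[transition]·ω^[nonsynonymous],
with F3x4 codon frequencies estimated from the data (floored at 1e−6
and renormalized over the 61 sense codons).  M8 draws ω per site from a
discretized Beta(p, q) — 10 equal-probability categories represented by
their category means — with probability p0, else from a point mass
ω_s ≥ 1; M8a fixes ω_s = 1; M0 has a single ω.  Branch lengths are in
expected substitutions per codon under the mixture-averaged rate.
Likelihoods use Felsenstein pruning with per-class eigendecomposition
of the reversible rate matrix and conditional rescaling; an exhaustive
ancestral-state summation verifies the pruning to < 1e−8 on small
trees.

Optimization is two-stage: M0 maximizes lnL over κ, ω and all branch
lengths (L-BFGS-B, finite-difference gradients) from an NJ start; M8a
and M8 then maximize their mixture parameters, κ and one branch-scale
factor on the M0 branch lengths.  Null and alternative get the same
treatment, and M8 is warm-started at the M8a optimum — where ω_s sits
at its boundary and leaves the likelihood unchanged — so
lnL(M8) ≥ lnL(M8a) holds at the reported optima (a numerical guard
enforces the nesting if the optimizer stalls).  `optimize_branches=False`
replaces the M0 branch optimization with a single scale factor on the
supplied lengths; the replicate studies use it with the generating
tree.  The LRT statistic 2ΔlnL is clamped at zero and referred to χ²
with 1 df — conservative relative to the 50:50 χ²₀/χ²₁ mixture, which
is why the realized type-I error sits well below the nominal level.

Site calls are naive empirical Bayes at the MLEs: per-site class
posteriors ∝ prior weight × class site-likelihood; a site is flagged
positive when the LRT is significant at 0.05, the ω_s-class posterior
is ≥ 0.95, and the posterior mean ω exceeds 1.  Gene divergence is the
arithmetic mean branch length of the M0 fit.  Nei–Gojobori (1986)
pathway counting with Jukes–Cantor correction provides a
counting-method ω independent of the ML machinery; the two agree in
rank across genes spanning purifying to positive selection.

NJ trees come from K2P distances (p-distance fallback at saturation)
via scikit-bio's neighbor joining, with negative branch lengths clamped
to zero.

## The synthetic plastome evolver

`build_ancestor` assembles a circular genome — defaults LSC 21.5 kb,
IR 5.4 kb, SSC 4.8 kb (LSC > IR > SSC, roughly one-fifth the scale of a
real orchid plastome, chosen to keep full-pipeline runs interactive) —
from a plastid-like gene plan: ~20 LSC genes (two with introns), five
IR genes including ndhB and rRNA, seven ndh genes in the SSC, rpl22
ending just short of the LSC/IRb junction, ycf1 crossing the SSC/IRa
junction by 402 bp with its reverse-complement fragment flush against
IRb/SSC, and IRa built as the exact reverse complement of IRb.  CDS
bodies are drawn AT-rich with a slight A bias, so pooled codon usage is
plastid-like (AAA the most common codon, A/T-ending codons over-used).
Six microsatellites (A, T, AT, TA, AAG, ATCC motifs) are planted in LSC
spacers with guard bases that pin their boundaries.

`evolve` runs the genome down a tree (default: eight taxa, total length
~0.036 substitutions/site, matching the per-100-bp mutation rates the
pipeline reports on real-scale data) with:

- **substitutions** — per branch and class, event counts are Poisson
  with mean multiplier × branch length × class size, sites uniform
  within class, replacement bases from the HKY conditional jump
  distribution (κ = 2, AT fraction 0.64).  Class multipliers default to
  CDS 0.72 : intron 1.0 : IGS 1.45, the observed ordering of per-class
  rates.  Substitutions sampled in either IR copy are applied to both
  (each IR site is sampled once), so the IRs stay identical;
- **indels** — events at rate 0.28 per eligible site per unit branch
  length with geometric lengths (p = 0.35), confined to IGS/intron in
  single-copy regions: coding indels would destroy reading frames, IR
  indels would break the mirroring coordinate pairing, and SSR columns
  belong to the slippage process;
- **SSR slippage** — per locus per branch, probability 0.3 of gaining
  or losing one motif unit;
- **ndh loss** — configured (branch, gene, delete|truncate) events;
  deletion removes the gene span (shrinking the SSC), truncation writes
  a premature stop and marks the lineage's copy a pseudogene.  The
  default study conditions delete four SSC ndh genes on one lineage and
  three on another, and truncate ndhF and ndhA elsewhere, mimicking
  independent ndh loss;
- **selection genes** — designated single-copy CDSs evolve under the
  GY94 M8 mixture along the same tree (default: two genes, ω_s 3.0 and
  2.5 with 10% and 5% positive sites) and are spliced into the genome,
  excluded from the nucleotide substitution process.

Every column carries an immutable key (insertions key between their
neighbors), so the emitted TruthLog reconstructs the exact multiple
alignment — degapping any leaf's row reproduces that leaf's genome
byte-for-byte — along with every substitution and indel event, planted
repeat and SSR coordinates, per-leaf SSR repeat counts, and per-site
true ω classes for selection genes.

What the generator does **not** emulate: AT-dependent mutation rates
(so the SV–AT correlation observed in real data is not reproduced in
simulation), rate heterogeneity within a class, genome rearrangement,
IR expansion/contraction as a mutational process (junction shifts in
detection arise only from chance flank matching), gene conversion
beyond perfect IR mirroring, and sequencing/assembly error.  Passing
tests therefore certify the statistics and detection machinery, not the
realism of any particular biological rate.

## Problem sizes in the test suite and acceptance script

Replicate studies run at desk scale, chosen once: LRT calibration — 60
replicates, 5 taxa, 90 codons, 5 beta categories; M8 parameter
recovery — 8 replicates, 8 taxa, 300 codons, 10 categories (mean ω_s
within 25% of truth and mean p0 within 0.10, tolerances fixed before
running); repeat-finder oracle — 50 sequences of ~360 bp with planted
near-duplicates of each class; the full synthetic study uses the
default 37.1 kb genome (`default_length_plan()`) with seed-pinned
fixtures shared across tests.  The acceptance script
reruns the published-table arithmetic and one full synthetic study plus
two single-gene selection scans.

## Numerical choices and degenerate inputs

- 0-based half-open coordinates internally; GenBank converts at the
  boundary.  Ambiguity codes other than N are rejected at read time.
- Pseudogenes paint CDS-class in the region map but are excluded from
  codon and selection analyses.
- Region-map overlaps resolve CDS > intron > IGS and are recorded.
- gc_content excludes N from numerator and denominator and raises on
  empty intervals; zero-variance inputs to regression/correlation raise
  rather than return NaN.
- Repeat-hit maximality is defined against the mismatch budget and
  sequence ends only; within-diagonal maximal windows are never nested,
  which is what makes oracle equality exact.
- F3x4 frequencies are floored at 1e−6 per position before
  renormalization so unobserved codons keep positive rates.
- `beta_category_means` clips category means into [1e−8, 1] to keep
  rate matrices non-degenerate at extreme shapes.
- Rounding for presentation is half-away-from-zero (`round_half_away`),
  and percentages print through `format_percent` at caller-chosen
  precision.

## Known limitations

- The M8/M8a machinery reproduces the published modeling framework,
  not any specific server's likelihood variants or priors; absolute
  lnL values are not comparable to other implementations, though LRT
  behavior and site calls are.
- ω_s is downward-biased at small alignments (few taxa, < 150 codons);
  the recovery study documents the scale at which estimates stabilize.
- The repeat finder's seed stage enumerates all exact 7-mer pair
  matches; highly repetitive low-complexity genomes (long poly-A
  tracts) inflate the candidate set and slow the scan.  `seed_len`
  trades completeness for speed if needed.
- `polymorphic_ssrs` uses greedy first-fit grouping; pathological flank
  similarity between distinct loci could merge groups.
- The evolver keeps IR copies exactly identical; real plastomes show
  occasional 1-bp copy differences, which is why reported IR length
  follows the IRb copy in table output.
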