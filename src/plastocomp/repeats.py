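"""Dispersed-repeat and microsatellite discovery.

Long repeats follow the REPuter conventions: forward = substring vs
substring, reverse = substring vs reversed substring (no complement),
palindromic = substring vs reverse-complemented substring; a hit is a
maximal pair of equal-length copies whose Hamming distance does not
exceed ``max_mismatch`` and whose length is at least ``min_len``.

SSRs are maximal perfect tandem runs of a 1-6 bp primitive motif meeting
a per-unit-length minimum repeat count (defaults 10/5/3/3/3/3).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from ._codon import revcomp

REPEAT_CLASSES = ("forward", "reverse", "palindromic")
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class RepeatHit:
    """One maximal long-repeat pair; intervals are 0-based half-open."""

    klass: str
    length: int
    mismatches: int
    pos1: tuple[int, int]
    pos2: tuple[int, int]
    region: str | None = None        # quadripartite region of each copy
    region2: str | None = None
    region_class: str | None = None  # CDS / intron / IGS of copy 1
    locus: str | None = None


@dataclass(frozen=True)
class SSRLocus:
    """One microsatellite locus (perfect tandem)."""

    motif: str           # canonical: minimal rotation over both strands
    raw_motif: str       # motif as it appears at ``start``
    unit: int
    count: int
    start: int
    end: int
    region: str | None = None
    region_class: str | None = None
    locus: str | None = None


# ---------------------------------------------------------------------------
# long repeats


def _maximal_windows(mm_sorted: list[int], lo: int, hi: int, k: int):
    """Maximal windows within [lo, hi] containing <= k mismatches.

    ``mm_sorted``: sorted mismatch positions inside [lo, hi].  Yields
    (start, end_inclusive, n_mismatches).
    """
    t = len(mm_sorted)
    if t <= k:
        yield lo, hi, t
        return
    p = [lo - 1] + mm_sorted + [hi + 1]
    for a in range(t - k + 1):
        ws = p[a] + 1
        we = p[a + k + 1] - 1
        yield ws, we, k


def _windows_around_seed(
    mismatch_at, seed: int, lo: int, hi: int, k: int, min_len: int
):
    """Maximal <=k-mismatch windows that contain position ``seed``.

    ``mismatch_at(x)`` tests the pairing at index x; the seed position
    itself must match.  Yields (ws, we, n_mismatches), we inclusive.
    """
    left = []  # nearest k+1 mismatches left of seed, descending
    x = seed - 1
    while x >= lo and len(left) < k + 1:
        if mismatch_at(x):
            left.append(x)
        x -= 1
    right = []
    x = seed + 1
    while x <= hi and len(right) < k + 1:
        if mismatch_at(x):
            right.append(x)
        x += 1
    for j in range(k + 1):
        # include j mismatches on the left, up to k-j on the right
        ws = left[j] + 1 if j < len(left) else lo
        nl = min(j, len(left))
        nr = min(k - nl, len(right))
        we = right[nr] - 1 if nr < len(right) else hi
        nm = nl + nr
        # maximal iff every extension is blocked by the (k+1)-th mismatch
        # or by the sequence end on both sides
        if (nm == k or (ws == lo and we == hi)) and we - ws + 1 >= min_len:
            yield ws, we, nm
        if j >= len(left):
            break


def _seed_buckets(seq: str, q: int) -> dict[str, list[int]]:
    buckets: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - q + 1):
        kmer = seq[i : i + q]
        if "N" not in kmer:
            buckets[kmer].append(i)
    return buckets


def find_long_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    classes: tuple[str, ...] = REPEAT_CLASSES,
) -> list[RepeatHit]:
    """All maximal repeat pairs of length >= min_len with <= max_mismatch.

    Seed-and-extend: any qualifying window carries an exact run of at
    least ceil((min_len - k)/(k + 1)) bases (pigeonhole), so exact
    q-mer matches of that length are complete seeds.  Each seed is
    extended to every maximal window containing it; duplicates from
    multiple seeds inside one run are removed by identity.
    """
    seq = seq.upper()
    n = len(seq)
    k = max_mismatch
    if n < min_len:
        return []
    q = max(1, -(-(min_len - k) // (k + 1)))
    buckets = _seed_buckets(seq, q)
    hits: set[tuple[str, int, int, int, int, int]] = set()

    if "forward" in classes:
        for positions in buckets.values():
            if len(positions) < 2:
                continue
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    i, j = positions[ai], positions[bi]
                    d = j - i
                    lo, hi = 0, n - d - 1

                    def mm(x, d=d):
                        return seq[x] != seq[x + d]

                    for ws, we, nm in _windows_around_seed(mm, i, lo, hi, k, min_len):
                        L = we - ws + 1
                        hits.add(("forward", ws, ws + L, ws + d, ws + d + L, nm))

    # reverse / palindromic: pairs (x, y), x < y, on anti-diagonal x+y=s.
    # A copy-pair ([i,i+L), [j,j+L)) pairs x=i+t with y=j+L-1-t; the first
    # copy is the window of x values, the second its mirror.
    for klass, xform in (("reverse", lambda c: c), ("palindromic", None)):
        if klass not in classes:
            continue
        if klass == "palindromic":
            other = seq.translate(str.maketrans("ACGT", "TGCA"))  # complement only
        else:
            other = seq
        # seeds: q-mer at i matching transformed q-mer ending at y
        tbuckets: dict[str, list[int]] = defaultdict(list)
        for j in range(n - q + 1):
            kmer = other[j : j + q][::-1]
            if "N" not in kmer:
                tbuckets[kmer].append(j)  # j = start of the mirrored q-mer
        for kmer, positions in buckets.items():
            mirrored = tbuckets.get(kmer)
            if not mirrored:
                continue
            for i in positions:
                for j in mirrored:
                    s = i + (j + q - 1)  # anti-diagonal index
                    lo = max(0, s - n + 1)
                    hi = min(n - 1, (s - 1) // 2, s)
                    if hi < lo:
                        continue
                    seed_x = i
                    if seed_x > hi or seed_x + q - 1 > hi:
                        # seed must lie wholly in the x-range (first copy)
                        continue

                    def mm(x, s=s, other=other):
                        return seq[x] != other[s - x]

                    for ws, we, nm in _windows_around_seed(
                        mm, seed_x, lo, hi, k, min_len
                    ):
                        L = we - ws + 1
                        hits.add((klass, ws, ws + L, s - we, s - ws + 1, nm))

    out = [
        RepeatHit(kl, e1 - s1, nm, (s1, e1), (s2, e2))
        for kl, s1, e1, s2, e2, nm in hits
    ]
    out.sort(key=lambda h: (h.pos1, h.pos2, h.klass))
    return out


def brute_force_long_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    classes: tuple[str, ...] = REPEAT_CLASSES,
) -> list[RepeatHit]:
    """Exhaustive per-diagonal enumeration (independent oracle, small inputs)."""
    seq = seq.upper()
    n = len(seq)
    k = max_mismatch
    hits: set[tuple[str, int, int, int, int, int]] = set()
    if "forward" in classes:
        for d in range(1, n):
            lo, hi = 0, n - d - 1
            if hi - lo + 1 < min_len:
                continue
            mms = [x for x in range(lo, hi + 1) if seq[x] != seq[x + d]]
            for ws, we, nm in _maximal_windows(mms, lo, hi, k):
                L = we - ws + 1
                if L >= min_len:
                    hits.add(("forward", ws, ws + L, ws + d, ws + d + L, nm))
    for klass in ("reverse", "palindromic"):
        if klass not in classes:
            continue
        other = (
            seq.translate(str.maketrans("ACGT", "TGCA")) if klass == "palindromic" else seq
        )
        for s in range(2 * n - 1):
            lo = max(0, s - n + 1)
            hi = min(n - 1, (s - 1) // 2)
            if hi - lo + 1 < min_len:
                continue
            mms = [x for x in range(lo, hi + 1) if seq[x] != other[s - x]]
            for ws, we, nm in _maximal_windows(mms, lo, hi, k):
                L = we - ws + 1
                if L >= min_len:
                    hits.add((klass, ws, ws + L, s - we, s - ws + 1, nm))
    out = [
        RepeatHit(kl, e1 - s1, nm, (s1, e1), (s2, e2))
        for kl, s1, e1, s2, e2, nm in hits
    ]
    out.sort(key=lambda h: (h.pos1, h.pos2, h.klass))
    return out


# ---------------------------------------------------------------------------
# SSRs


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    cands = []
    for m in (motif, revcomp(motif)):
        cands.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(cands)


def scan_ssrs(
    seq: str, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """Maximal perfect tandem repeats of primitive 1-6 bp motifs.

    A run is reported once, at its smallest (primitive) unit length, so a
    poly-A run is a mononucleotide locus, never (AA)n.
    """
    seq = seq.upper()
    if thresholds is None:
        thresholds = DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    loci: list[SSRLocus] = []
    for u, min_count in sorted(thresholds.items()):
        x = 0
        while x < n - u:
            if seq[x] == seq[x + u] and seq[x] != "N":
                a = x
                while x < n - u and seq[x] == seq[x + u] and seq[x] != "N":
                    x += 1
                b = x  # match run [a, b)
                span = b - a + u
                count = span // u
                motif = seq[a : a + u]
                if count >= min_count and _is_primitive(motif):
                    loci.append(
                        SSRLocus(
                            motif=canonical_motif(motif),
                            raw_motif=motif,
                            unit=u,
                            count=count,
                            start=a,
                            end=a + count * u,
                        )
                    )
            else:
                x += 1
    loci.sort(key=lambda l: (l.start, l.unit))
    return loci


# ---------------------------------------------------------------------------
# region classification of hits/loci


def _majority_region(start: int, end: int, partition) -> str:
    """Quadripartite region by majority overlap; lower-coordinate wins ties."""
    best = None
    for name in ("LSC", "IRb", "SSC", "IRa"):
        s, e = partition.interval(name)
        ov = _overlap_len(start, end, s, e, partition.genome_length)
        if best is None or ov > best[0] or (ov == best[0] and s < best[2]):
            best = (ov, name, s)
    return best[1]


def _overlap_len(a0, a1, b0, b1, n):
    if b0 <= b1:
        return max(0, min(a1, b1) - max(a0, b0))
    # wrapped region
    return max(0, min(a1, n) - max(a0, b0)) + max(0, min(a1, b1) - a0)


def _majority_class(start: int, end: int, region_map) -> tuple[str, str]:
    best = (0, "IGS", "")
    for s, e, cls, locus in region_map.intervals:
        ov = max(0, min(end, e) - max(start, s))
        if ov > best[0]:
            best = (ov, cls, locus)
    return best[1], best[2]


def classify_hits(items, partition, region_map):
    """Annotate repeat hits / SSR loci with quadripartite region and class.

    Returns (annotated items, summary dict of (region, class) -> count),
    counting each item once by its first copy.
    """
    annotated = []
    summary: dict[tuple[str, str], int] = defaultdict(int)
    for it in items:
        if isinstance(it, RepeatHit):
            r1 = _majority_region(*it.pos1, partition)
            r2 = _majority_region(*it.pos2, partition)
            cls, locus = _majority_class(*it.pos1, region_map)
            it = replace(it, region=r1, region2=r2, region_class=cls, locus=locus)
            key_region = r1
        else:
            r = _majority_region(it.start, it.end, partition)
            cls, locus = _majority_class(it.start, it.end, region_map)
            it = replace(it, region=r, region_class=cls, locus=locus)
            key_region = r
        region_group = "IR" if key_region in ("IRa", "IRb") else key_region
        summary[(region_group, it.region_class)] += 1
        annotated.append(it)
    return annotated, dict(summary)


# ---------------------------------------------------------------------------
# cross-species polymorphic SSRs


@dataclass
class SSRGroup:
    """One cross-species homologous SSR locus group."""

    motif: str
    left_flank: str
    right_flank: str
    counts: dict[str, int] = field(default_factory=dict)  # species -> repeat count
    positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.counts)

    @property
    def polymorphic(self) -> bool:
        return len(set(self.counts.values())) >= 2


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def polymorphic_ssrs(
    per_species: dict[str, tuple[str, list[SSRLocus]]],
    flank_len: int = 20,
    min_species: int = 4,
    max_flank_mismatch: int = 2,
) -> list[SSRGroup]:
    """Group SSR loci across species and keep polymorphic groups.

    Loci join a group when canonical motifs match and either flanking
    ``flank_len``-mer matches the group's with <= ``max_flank_mismatch``
    mismatches.  A group is reported when present in >= ``min_species``
    species with >= 2 distinct repeat counts.
    """
    groups: list[SSRGroup] = []
    for species, (seq, loci) in per_species.items():
        for loc in loci:
            lf = seq[max(0, loc.start - flank_len) : loc.start]
            rf = seq[loc.end : loc.end + flank_len]
            placed = False
            for g in groups:
                if g.motif != loc.motif or species in g.counts:
                    continue
                if (
                    _hamming(lf, g.left_flank) <= max_flank_mismatch
                    or _hamming(rf, g.right_flank) <= max_flank_mismatch
                ):
                    g.counts[species] = loc.count
                    g.positions[species] = (loc.start, loc.end)
                    placed = True
                    break
            if not placed:
                groups.append(
                    SSRGroup(
                        motif=loc.motif,
                        left_flank=lf,
                        right_flank=rf,
                        counts={species: loc.count},
                        positions={species: (loc.start, loc.end)},
                    )
                )
    return [g for g in groups if g.n_species >= min_species and g.polymorphic]


def ssr_flanks_fasta(seq: str, loci: list[SSRLocus], path, flank_len: int = 150) -> None:
    """Write SSR loci with their flanks as FASTA (external primer design)."""
    with open(path, "w") as fh:
        for i, loc in enumerate(loci):
            a = max(0, loc.start - flank_len)
            b = min(len(seq), loc.end + flank_len)
            fh.write(f">ssr_{i}|{loc.motif}x{loc.count}|{loc.start}-{loc.end}\n")
            fh.write(seq[a:b] + "\n")


# ---------------------------------------------------------------------------
# primer constraint validation


DEFAULT_PRIMER_RULES = {
    "product": (100, 500),
    "length": (18, 27),
    "gc": (40.0, 60.0),
    "tm_diff": 1.0,
}


@dataclass(frozen=True)
class PrimerConstraintReport:
    rules: dict
    passed: dict

    @property
    def ok(self) -> bool:
        return all(self.passed.values())


def primer_tm(primer: str) -> float:
    """Simple salt-free melting temperature: 64.9 + 41*(GC - 16.4)/len."""
    if not primer:
        raise ValueError("empty primer")
    gc = primer.upper().count("G") + primer.upper().count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def check_primer_constraints(
    forward: str,
    reverse: str,
    product_length: int,
    rules: dict | None = None,
) -> PrimerConstraintReport:
    """Evaluate amplification-product and primer-pair constraints."""
    if not forward or not reverse:
        raise ValueError("empty primer")
    if rules is None:
        rules = DEFAULT_PRIMER_RULES
    plo, phi = rules["product"]
    llo, lhi = rules["length"]
    gclo, gchi = rules["gc"]

    def gc_pct(p: str) -> float:
        p = p.upper()
        return 100.0 * (p.count("G") + p.count("C")) / len(p)

    passed = {
        "product": plo <= product_length <= phi,
        "length": llo <= len(forward) <= lhi and llo <= len(reverse) <= lhi,
        "gc": gclo <= gc_pct(forward) <= gchi and gclo <= gc_pct(reverse) <= gchi,
        "tm_diff": abs(primer_tm(forward) - primer_tm(reverse)) <= rules["tm_diff"],
    }
    return PrimerConstraintReport(rules=dict(rules), passed=passed)
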