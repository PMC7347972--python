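"""Quadripartite structure detection and junction analysis.

A plastome is decomposed into LSC / IRb / SSC / IRa by locating the
maximal pair of inverted-repeat copies (one copy matching the reverse
complement of the other within a mismatch fraction).  Junctions follow
the convention that the genome reads LSC, IRb, SSC, IRa around the
circle: J_LB = LSC/IRb, J_SB = IRb/SSC, J_SA = SSC/IRa, J_LA = IRa/LSC.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._codon import revcomp, translate
from .genome_io import PlastomeRecord, Feature, extract_feature_sequence

NDH_GENES = (
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
    "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK",
)

JUNCTIONS = ("J_LB", "J_SB", "J_SA", "J_LA")


class NoQuadripartiteStructure(ValueError):
    """No inverted-repeat pair of the required size was found."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the linearized genome.

    Intervals are [start, end) with end taken modulo the genome length;
    an interval with end <= start wraps through the origin.
    """

    genome_length: int
    LSC: tuple[int, int]
    IRb: tuple[int, int]
    SSC: tuple[int, int]
    IRa: tuple[int, int]

    def interval(self, name: str) -> tuple[int, int]:
        return getattr(self, name)

    def region_length(self, name: str) -> int:
        s, e = self.interval(name)
        return (e - s) % self.genome_length or self.genome_length

    @property
    def lengths(self) -> dict[str, int]:
        return {r: self.region_length(r) for r in ("LSC", "IRb", "SSC", "IRa")}

    def ir_length(self) -> int:
        """One reported IR length (the IRb copy), Table-style."""
        return self.region_length("IRb")

    def junction_position(self, junction: str) -> int:
        """0-based position of the first base after the junction."""
        n = self.genome_length
        if junction == "J_LB":
            return self.IRb[0] % n
        if junction == "J_SB":
            return self.SSC[0] % n
        if junction == "J_SA":
            return self.IRa[0] % n
        if junction == "J_LA":
            return self.LSC[0] % n
        raise ValueError(f"unknown junction {junction!r}")

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        pos %= n
        for name in ("LSC", "IRb", "SSC", "IRa"):
            s, e = self.interval(name)
            if s < e:
                if s <= pos < e:
                    return name
            elif pos >= s or pos < e:
                return name
        raise ValueError(f"position {pos} not covered")


# ---------------------------------------------------------------------------
# IR detection (seed and extend on the sequence vs its complement)


def detect_inverted_repeat(
    record: PlastomeRecord | str,
    min_len: int = 10_000,
    max_mismatch_frac: float = 0.01,
    seed_len: int = 25,
) -> QuadripartitePartition:
    """Locate the IR pair and return the quadripartite partition.

    Seed-and-extend: exact ``seed_len``-mer matches between the sequence
    and its reverse complement nominate anti-diagonals; each candidate
    is extended outward while the running mismatch fraction stays within
    ``max_mismatch_frac``.  The longest extended pair wins; ties break
    by leftmost IRb start.  Wrapping through the origin is handled by
    searching the doubled sequence.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record.upper()
    n = len(seq)
    if n < 2 * min_len:
        raise NoQuadripartiteStructure(f"genome ({n} bp) shorter than 2*min_len")
    dbl = seq + seq
    comp = dbl.translate(str.maketrans("ACGTN", "TGCAN"))

    # index seed_len-mers of the (single-copy) sequence
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        index[dbl[i : i + seed_len]].append(i)
    # anti-diagonals supported by seeds: seq[x] pairs with comp[s-x]
    diag_votes: dict[int, list[int]] = defaultdict(list)
    for j in range(2 * n - seed_len + 1):
        kmer = comp[j : j + seed_len][::-1]
        for i in index.get(kmer, ()):
            s = i + j + seed_len - 1
            if i < (s + 1) // 2:  # keep each unordered pair once
                diag_votes[s].append(i)

    stall = 200  # stop a phase after this many steps without a valid frontier

    def extend(s: int, x0: int) -> tuple[int, int]:
        """Maximal window around x0 whose mismatch fraction stays bounded.

        Each phase walks outward tracking the furthest match position at
        which the whole window still satisfies the fraction, and gives up
        once the frontier has not advanced for ``stall`` steps.
        """
        lo = max(0, s - (2 * n - 1))
        hi = min(2 * n - 1, (s - 1) // 2)
        # right phase: window [x0, frontier]
        frontier = x0
        mm_right = 0
        mm_seen = 0
        pos = x0
        while pos < hi and pos - frontier < stall:
            pos += 1
            if dbl[pos] != comp[s - pos]:
                mm_seen += 1
            elif mm_seen <= max_mismatch_frac * (pos - x0 + 1):
                frontier = pos
                mm_right = mm_seen
        we = frontier
        # left phase: window [frontier, we]
        frontier = x0
        mm_seen = mm_right
        pos = x0
        while pos > lo and frontier - pos < stall:
            pos -= 1
            if dbl[pos] != comp[s - pos]:
                mm_seen += 1
            elif mm_seen <= max_mismatch_frac * (we - pos + 1):
                frontier = pos
        return frontier, we

    candidates: list[tuple[int, int, int, int]] = []  # (length, s1, ws, we)
    seen_spans: set[tuple[int, int]] = set()
    best_len = 0
    # strongest diagonals first
    for s, votes in sorted(diag_votes.items(), key=lambda kv: -len(kv[1])):
        if best_len and len(votes) * seed_len < best_len // 2:
            break
        votes = sorted(votes)
        x0 = votes[len(votes) // 2]
        ws, we = extend(s, x0)
        L = we - ws + 1
        if L >= min_len and (ws, we) not in seen_spans:
            seen_spans.add((ws, we))
            candidates.append((L, s, ws, we))
            best_len = max(best_len, L)

    if not candidates:
        raise NoQuadripartiteStructure(
            f"no inverted repeat >= {min_len} bp at mismatch fraction "
            f"{max_mismatch_frac}"
        )
    # longest wins; ties by leftmost first-copy start
    candidates.sort(key=lambda c: (-c[0], c[2]))
    L, s, ws, we = candidates[0]
    copy1 = (ws % n, (we + 1) % n)          # first copy (lower coords)
    copy2 = ((s - we) % n, (s - ws + 1) % n)

    def gap(a_end: int, b_start: int) -> tuple[int, int]:
        return (a_end % n, b_start % n)

    gap12 = gap(we + 1, s - we)        # between copy1 end and copy2 start
    gap21 = gap(s - ws + 1, ws + n)    # between copy2 end and copy1 start
    len12 = (gap12[1] - gap12[0]) % n
    len21 = (gap21[1] - gap21[0]) % n
    if len12 == 0 or len21 == 0:
        raise NoQuadripartiteStructure("IR copies leave no single-copy region")
    if len12 >= len21:
        lsc, ssc = gap12, gap21
        irb, ira = copy2, copy1  # LSC precedes IRb: copy after LSC is IRb
    else:
        lsc, ssc = gap21, gap12
        irb, ira = copy1, copy2
    return QuadripartitePartition(n, LSC=lsc, IRb=irb, SSC=ssc, IRa=ira)


# ---------------------------------------------------------------------------
# junction context


@dataclass(frozen=True)
class JunctionContext:
    """Gene context at one junction.

    ``overlap`` is the signed bp of the feature inside the IR: positive
    when the feature extends into the IR, negative = distance between
    the feature and the junction (feature wholly outside the IR).
    """

    junction: str
    feature: str | None
    overlap: int | None


def _circ_interval_overlap(fs: int, fe: int, rs: int, re: int, n: int) -> int:
    """Overlap length of genome intervals allowing wrap on the region."""
    spans = [(rs, re)] if rs < re else [(rs, n), (0, re)]
    fspans = [(fs, fe)] if fs < fe else [(fs, n), (0, fe)]
    total = 0
    for a0, a1 in fspans:
        for b0, b1 in spans:
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


def junction_report(
    record: PlastomeRecord,
    partition: QuadripartitePartition,
    search_window: int = 1000,
) -> list[JunctionContext]:
    """Overlapping (or nearest, within 1 kb) feature at each junction."""
    n = partition.genome_length
    out = []
    ir_of = {"J_LB": "IRb", "J_SB": "IRb", "J_SA": "IRa", "J_LA": "IRa"}
    for j in JUNCTIONS:
        pos = partition.junction_position(j)
        irs, ire = partition.interval(ir_of[j])
        best: tuple[int, Feature] | None = None  # (distance, feature)
        for f in record.features:
            fs, fe = f.start, f.end
            if f.wraps:
                inside_f = pos >= fs or pos < fe
            else:
                inside_f = fs <= pos < fe
            if inside_f:
                dist = 0
            else:
                dist = min((fs - pos) % n, (pos - (fe - 1)) % n)
            if dist <= search_window and (best is None or dist < best[0]):
                best = (dist, f)
        if best is None:
            out.append(JunctionContext(j, None, None))
            continue
        f = best[1]
        inside = sum(_circ_interval_overlap(s, e, irs, ire, n) for s, e in f.parts)
        if inside > 0:
            overlap = inside
        else:
            overlap = -min((irs - f.end) % n, (f.start - ire) % n)
        out.append(JunctionContext(j, f.name, overlap))
    return out


# ---------------------------------------------------------------------------
# IR/SSC junction typology


@dataclass(frozen=True)
class IrSscType:
    """The ndhF-based IR/SSC junction type (1, 2 or 3)."""

    type_number: int
    description: str


def classify_ir_ssc_type(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> IrSscType:
    """Type 1: ndhF present, not overlapping J_SB; Type 2: ndhF spans
    J_SB; Type 3: ndhF lost (IR expanded toward ycf1)."""
    ndhf = record.features_named("ndhF")
    if not ndhf:
        return IrSscType(3, "ndhF lost; IR expands toward ycf1")
    pos = partition.junction_position("J_SB")
    n = partition.genome_length
    for f in ndhf:
        for s, e in f.parts:
            if s <= pos < e:
                return IrSscType(2, "ndhF overlaps the IRb/SSC junction")
        if f.wraps and (pos >= f.start or pos < f.end):
            return IrSscType(2, "ndhF overlaps the IRb/SSC junction")
    return IrSscType(1, "ndhF present in SSC, not overlapping the junction")


# ---------------------------------------------------------------------------
# ndh intactness audit


def ndh_audit(
    records: list[PlastomeRecord],
    reference_lengths: dict[str, int],
    min_fraction: float = 0.9,
) -> dict[str, dict[str, str]]:
    """Per-genome, per-gene status of the 11 ndh genes.

    intact = annotated CDS with an ATG/GTG start, no internal stop, and
    length >= ``min_fraction`` of the reference; truncated = a feature is
    present but fails those checks; lost = no feature at all.
    """
    out: dict[str, dict[str, str]] = {}
    for rec in records:
        row: dict[str, str] = {}
        for gene in NDH_GENES:
            feats = rec.features_named(gene)
            if not feats:
                row[gene] = "lost"
                continue
            status = "truncated"
            for f in feats:
                if f.kind != "CDS":
                    continue
                ref = reference_lengths.get(gene)
                seq = extract_feature_sequence(rec, f)
                aa = translate(seq)
                ok_start = seq[:3] in ("ATG", "GTG")
                no_internal_stop = "*" not in aa[:-1]
                long_enough = ref is None or len(seq) >= min_fraction * ref
                if ok_start and no_internal_stop and long_enough:
                    status = "intact"
                    break
            row[gene] = status
        out[rec.id] = row
    return out


# ---------------------------------------------------------------------------
# length statistics


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def length_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with r2 and F(1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = len(x)
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 * (n - 2) / (1 - r2)
        p = stats.f.sf(f, 1, n - 2)
    return RegressionResult(res.slope, res.intercept, r2, f, (1, n - 2), p)


def ndh_ssc_correlation(
    records: list[PlastomeRecord],
    partitions: dict[str, QuadripartitePartition],
) -> tuple[float, float]:
    """Pearson r between summed residual ndh length in the SSC and SSC length."""
    xs, ys = [], []
    for rec in records:
        part = partitions[rec.id]
        total = 0
        for gene in NDH_GENES:
            for f in rec.features_named(gene):
                for s, e in f.parts:
                    mid = (s + e) // 2
                    if part.region_of(mid) == "SSC":
                        total += e - s
        xs.append(total)
        ys.append(part.region_length("SSC"))
    if len(xs) < 3:
        raise ValueError("need >= 3 genomes")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
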