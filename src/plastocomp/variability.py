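"""Alignment segmentation and sequence-variability marker ranking.

"Mutations" is the minimum mutation count Eta: the sum over gap-free
columns of (number of distinct states - 1).  Indels are counted as
events by simple indel coding: one event per distinct gap span (same
start and end columns), however many sequences share it.  SV is

    SV = 100 * (Eta + indel events) / (conserved + Eta + indel events)

with conserved = gap-free monomorphic columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import RegionClassMap

GAP = ord("-")
_ACGT = frozenset(b"ACGT")


def _matrix(rows: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).upper().encode(), dtype=np.uint8)
    return arr.reshape(len(rows), -1)


def round_half_away(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: float, denominator: float, decimals: int = 2) -> str:
    """Report-style percentage: round half away from zero, trim '.0'."""
    pct = round_half_away(100.0 * numerator / denominator, decimals)
    if decimals == 0 or pct == int(pct):
        return f"{int(round(pct))}%" if decimals == 0 else f"{pct:g}%"
    return f"{pct}%"


# ---------------------------------------------------------------------------
# column statistics


def _column_states(mat: np.ndarray):
    """Per gap-free column: set of distinct A/C/G/T states (N ignored)."""
    nseq, ncol = mat.shape
    gap_free = ~(mat == GAP).any(axis=0)
    for j in np.nonzero(gap_free)[0]:
        col = mat[:, j]
        states = frozenset(col.tobytes()) & _ACGT
        yield j, col, states


def count_mutations(rows: list[str]) -> int:
    """Eta: sum over gap-free columns of (distinct states - 1)."""
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    total = 0
    for _, _, states in _column_states(_matrix(rows)):
        if states:
            total += len(states) - 1
    return total


def count_conserved(rows: list[str]) -> int:
    """Gap-free monomorphic columns."""
    total = 0
    for _, _, states in _column_states(_matrix(rows)):
        if len(states) == 1:
            total += 1
    return total


def count_indel_events(rows: list[str]) -> int:
    """Simple indel coding: one event per distinct gap span (start, end)."""
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    spans: set[tuple[int, int]] = set()
    for row in rows:
        j = 0
        n = len(row)
        while j < n:
            if row[j] == "-":
                a = j
                while j < n and row[j] == "-":
                    j += 1
                spans.add((a, j))
            else:
                j += 1
    return len(spans)


def count_pis(rows: list[str]) -> int:
    """Parsimony-informative sites: gap-free columns with >= 2 states
    each carried by >= 2 sequences."""
    total = 0
    for _, col, states in _column_states(_matrix(rows)):
        if len(states) < 2:
            continue
        informative_states = sum(
            1 for s in states if int((col == s).sum()) >= 2
        )
        if informative_states >= 2:
            total += 1
    return total


def at_fraction(rows: list[str]) -> float:
    mat = _matrix(rows)
    at = np.isin(mat, np.frombuffer(b"AT", dtype=np.uint8)).sum()
    acgt = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)).sum()
    return float(at / acgt) if acgt else float("nan")


# ---------------------------------------------------------------------------
# segments


@dataclass
class AlignedSegment:
    """One CDS/intron/IGS slice of the master alignment with statistics."""

    name: str
    klass: str
    col_start: int
    col_end: int
    n_sequences: int
    aligned_length: int
    ref_length: int
    mutations: int
    indel_events: int
    conserved_sites: int
    pis: int
    at: float
    rows: list[str] = field(repr=False, default_factory=list)

    @property
    def sv(self) -> float | None:
        return sequence_variability(self)


def sequence_variability(segment: AlignedSegment) -> float | None:
    """SV percent; None when the denominator is zero."""
    num = segment.mutations + segment.indel_events
    den = segment.conserved_sites + num
    return 100.0 * num / den if den else None


def _segment_stats(name, klass, c0, c1, rows) -> AlignedSegment:
    sub = [r[c0:c1] for r in rows]
    return AlignedSegment(
        name=name,
        klass=klass,
        col_start=c0,
        col_end=c1,
        n_sequences=len(rows),
        aligned_length=c1 - c0,
        ref_length=len(sub[0]) - sub[0].count("-"),
        mutations=count_mutations(sub),
        indel_events=count_indel_events(sub),
        conserved_sites=count_conserved(sub),
        pis=count_pis(sub),
        at=at_fraction(sub),
        rows=sub,
    )


def segment_alignment(
    alignment: dict[str, str],
    reference_map: RegionClassMap,
    reference_id: str | None = None,
    min_len: int = 150,
    max_gap_fraction: float = 0.9,
) -> list[AlignedSegment]:
    """Project the reference's CDS/intron/IGS intervals onto alignment
    columns and keep segments with ungapped reference length >= min_len.

    A segment is dropped when any sequence is almost entirely gap inside
    it (> ``max_gap_fraction``), the footprint of a rearrangement or a
    region absent from that genome.
    """
    if reference_id is None:
        reference_id = reference_map.seq_id
    if reference_id not in alignment:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    names = list(alignment)
    rows = [alignment[n] for n in names]
    ref_row = alignment[reference_id]
    # reference position -> alignment column
    ref_cols = [j for j, ch in enumerate(ref_row) if ch != "-"]
    if len(ref_cols) != reference_map.length:
        raise ValueError(
            "degapped reference row length does not match the region map"
        )
    segments = []
    for s, e, cls, locus in reference_map.intervals:
        if e - s < min_len:
            continue
        c0, c1 = ref_cols[s], ref_cols[e - 1] + 1
        seg = _segment_stats(locus, cls, c0, c1, rows)
        gappy = any(
            r.count("-") > max_gap_fraction * len(r) for r in (row[c0:c1] for row in rows)
        )
        if not gappy:
            segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# rate table and ranking


@dataclass(frozen=True)
class RateTable:
    """Pooled per-class mutation/indel counts and per-100-bp rates."""

    table: pd.DataFrame

    @staticmethod
    def from_counts(rows: dict[str, tuple[int, int, int]]) -> "RateTable":
        """rows: class -> (mutations, indels, total_length)."""
        recs = []
        for cls, (mut, ind, length) in rows.items():
            recs.append(
                {
                    "class": cls,
                    "mutations": mut,
                    "indels": ind,
                    "total_length": length,
                    "mutations_per_100bp": 100.0 * mut / length if length else 0.0,
                    "indels_per_100bp": 100.0 * ind / length if length else 0.0,
                }
            )
        return RateTable(pd.DataFrame(recs).set_index("class"))

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("mutations_per_100bp", "indels_per_100bp"):
            out[col] = [round_half_away(v, decimals) for v in out[col]]
        return out


def rate_table(segments: list[AlignedSegment]) -> RateTable:
    pooled: dict[str, list[int]] = {}
    for seg in segments:
        agg = pooled.setdefault(seg.klass, [0, 0, 0])
        agg[0] += seg.mutations
        agg[1] += seg.indel_events
        agg[2] += seg.ref_length
    return RateTable.from_counts({k: tuple(v) for k, v in pooled.items()})


def rank_segments(segments: list[AlignedSegment], k: int = 10) -> list[AlignedSegment]:
    """Top-k by SV, ties by PIS, then length, then name."""
    ordered = sorted(
        segments,
        key=lambda s: (
            -(s.sv if s.sv is not None else -1.0),
            -s.pis,
            -s.aligned_length,
            s.name,
        ),
    )
    return ordered[: min(k, len(ordered))]


def sv_at_correlation(segments: list[AlignedSegment]) -> tuple[float, float]:
    """Pearson r between SV and AT fraction across segments."""
    pairs = [(s.sv, s.at) for s in segments if s.sv is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 segments with defined SV")
    sv, at = zip(*pairs)
    if np.ptp(at) == 0 or np.ptp(sv) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(sv, at)
    return float(r), float(p)


def segments_frame(segments: list[AlignedSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "class": s.klass,
                "aligned_length": s.aligned_length,
                "ref_length": s.ref_length,
                "mutations": s.mutations,
                "indels": s.indel_events,
                "conserved": s.conserved_sites,
                "pis": s.pis,
                "at": s.at,
                "sv": s.sv,
            }
            for s in segments
        ]
    )
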