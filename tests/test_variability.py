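import numpy as np
import pytest

from plastocomp.genome_io import region_class_map
from plastocomp.variability import (
    AlignedSegment,
    RateTable,
    at_fraction,
    count_conserved,
    count_indel_events,
    count_mutations,
    count_pis,
    format_percent,
    rank_segments,
    rate_table,
    segment_alignment,
    sequence_variability,
    sv_at_correlation,
)


# --- column statistics vs independent per-column oracles -------------------


def _oracle_counts(rows):
    """Brute-force per-column recount, independent of the implementation."""
    ncol = len(rows[0])
    eta = conserved = pis = 0
    for j in range(ncol):
        col = [r[j] for r in rows]
        if "-" in col:
            continue
        states = {c for c in col if c in "ACGT"}
        if states:
            eta += len(states) - 1
        if len(states) == 1:
            conserved += 1
        if len(states) >= 2:
            if sum(1 for s in states if col.count(s) >= 2) >= 2:
                pis += 1
    spans = set()
    for r in rows:
        j = 0
        while j < ncol:
            if r[j] == "-":
                a = j
                while j < ncol and r[j] == "-":
                    j += 1
                spans.add((a, j))
            else:
                j += 1
    return eta, conserved, pis, len(spans)


def test_column_contribution_is_states_minus_one():
    rows = ["A", "A", "G", "T"]
    assert count_mutations(rows) == 2


def test_identical_sequences_have_zero_mutations():
    rows = ["ACGTACGT"] * 5
    assert count_mutations(rows) == 0
    assert count_conserved(rows) == 8


@pytest.mark.parametrize("seed", range(6))
def test_random_alignment_matches_per_column_oracle(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(8):
        row = rng.choice(list("ACGT-"), size=500, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        rows.append("".join(row))
    eta, conserved, pis, indels = _oracle_counts(rows)
    assert count_mutations(rows) == eta
    assert count_conserved(rows) == conserved
    assert count_pis(rows) == pis
    assert count_indel_events(rows) == indels
    assert pis <= eta


def test_indel_event_endpoint_rule():
    rows = ["AAAAAAAAAA", "AAAAA---AA", "AAAAA---AA", "AAAAA----A"]
    # [5,8) shared by two sequences counts once; [5,9) separately
    assert count_indel_events(rows) == 2
    one = ["AAAAAAAAAA", "AAAAA---AA"]
    assert count_indel_events(one) == 1


def test_pis_examples():
    assert count_pis(["A", "A", "T", "T"]) == 1
    assert count_pis(["A", "A", "A", "T"]) == 0


def test_sequence_variability_formula():
    seg = AlignedSegment(
        name="x", klass="IGS", col_start=0, col_end=100, n_sequences=8,
        aligned_length=100, ref_length=100, mutations=10, indel_events=2,
        conserved_sites=88, pis=5, at=0.6,
    )
    assert seg.sv == pytest.approx(12.0)
    zero = AlignedSegment(
        name="z", klass="IGS", col_start=0, col_end=200, n_sequences=8,
        aligned_length=200, ref_length=200, mutations=0, indel_events=0,
        conserved_sites=200, pis=0, at=0.5,
    )
    assert zero.sv == 0.0
    empty = AlignedSegment(
        name="e", klass="IGS", col_start=0, col_end=0, n_sequences=8,
        aligned_length=0, ref_length=0, mutations=0, indel_events=0,
        conserved_sites=0, pis=0, at=0.5,
    )
    assert sequence_variability(empty) is None


def test_sv_internal_consistency_on_study_segments(study, study_records):
    _, records, truth = study
    aln = truth.alignment(include_ancestor=False)
    ref = records[0]
    segs = segment_alignment(aln, region_class_map(ref), ref.id)
    assert len(segs) > 20
    for seg in segs:
        num = seg.mutations + seg.indel_events
        den = seg.conserved_sites + num
        expect = 100.0 * num / den if den else None
        assert seg.sv == expect


def test_segment_length_boundary(study, study_records):
    _, records, truth = study
    aln = truth.alignment(include_ancestor=False)
    ref = records[0]
    m = region_class_map(ref)
    segs150 = segment_alignment(aln, m, ref.id, min_len=150)
    for s in segs150:
        assert s.ref_length >= 150
    # raising the threshold strictly filters
    segs400 = segment_alignment(aln, m, ref.id, min_len=400)
    assert {s.name for s in segs400} <= {s.name for s in segs150}


def test_rate_table_pooled_counts_equal_sum_of_segments(study, study_records):
    _, records, truth = study
    aln = truth.alignment(include_ancestor=False)
    ref = records[0]
    segs = segment_alignment(aln, region_class_map(ref), ref.id)
    rt = rate_table(segs)
    for cls in rt.table.index:
        mine = rt.table.loc[cls]
        subs = [s for s in segs if s.klass == cls]
        assert mine.mutations == sum(s.mutations for s in subs)
        assert mine.indels == sum(s.indel_events for s in subs)
        assert mine.mutations_per_100bp == pytest.approx(
            100 * mine.mutations / mine.total_length
        )


def test_rank_segments_tie_breaking():
    def seg(name, sv_counts, pis, length):
        mut, cons = sv_counts
        return AlignedSegment(
            name=name, klass="IGS", col_start=0, col_end=length,
            n_sequences=4, aligned_length=length, ref_length=length,
            mutations=mut, indel_events=0, conserved_sites=cons, pis=pis, at=0.5,
        )

    a = seg("alpha", (10, 90), 5, 100)
    b = seg("beta", (10, 90), 7, 100)   # same SV, higher PIS
    c = seg("gamma", (20, 80), 1, 100)  # highest SV
    d = seg("delta", (10, 90), 5, 100)  # ties alpha through PIS+length: name
    ranked = rank_segments([a, b, c, d], k=10)
    assert [s.name for s in ranked] == ["gamma", "beta", "alpha", "delta"]


def test_rank_k_larger_than_set_returns_all():
    segs = rank_segments([], k=5)
    assert segs == []


def test_planted_high_rate_segment_ranks_first():
    rng = np.random.default_rng(0)
    base = "".join(rng.choice(list("ACGT"), size=200))
    quiet = [base] * 6
    noisy = []
    for i in range(6):
        row = list(base)
        for p in rng.choice(200, size=30, replace=False):
            row[p] = "ACGT"[(("ACGT".index(row[p])) + 1 + i) % 4]
        noisy.append("".join(row))

    def mk(name, rows):
        from plastocomp.variability import _segment_stats

        return _segment_stats(name, "IGS", 0, len(rows[0]), rows)

    segs = [mk("quiet", quiet), mk("hot", noisy)]
    assert rank_segments(segs, 1)[0].name == "hot"


def test_sv_at_correlation_errors_and_construction():
    rng = np.random.default_rng(1)
    segs = []
    for i in range(30):
        at = 0.4 + 0.02 * i
        mut = int(2 + 100 * (at - 0.4))
        segs.append(
            AlignedSegment(
                name=f"s{i}", klass="IGS", col_start=0, col_end=200,
                n_sequences=8, aligned_length=200, ref_length=200,
                mutations=mut, indel_events=0, conserved_sites=200 - mut,
                pis=0, at=at + rng.normal(0, 0.002),
            )
        )
    r, p = sv_at_correlation(segs)
    assert r > 0.9
    flat = [
        AlignedSegment(
            name=f"f{i}", klass="IGS", col_start=0, col_end=100, n_sequences=4,
            aligned_length=100, ref_length=100, mutations=i, indel_events=0,
            conserved_sites=100 - i, pis=0, at=0.5,
        )
        for i in range(5)
    ]
    with pytest.raises(ValueError):
        sv_at_correlation(flat)


def test_report_percentage_formatting():
    assert format_percent(2429, 163916, decimals=2) == "1.48%"
    assert format_percent(285, 7087, decimals=0) == "4%"
    assert format_percent(1, 8, decimals=2) == "12.5%"


def test_rate_table_rounding_half_away():
    rt = RateTable.from_counts({"IGS": (125, 0, 10000)})  # 1.25 exactly
    assert rt.rounded(1).loc["IGS", "mutations_per_100bp"] == 1.3
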