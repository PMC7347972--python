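import numpy as np
import pytest

from plastocomp._codon import revcomp
from plastocomp.genome_io import region_class_map
from plastocomp.synthetic import (
    ConfigError,
    EvolutionConfig,
    build_ancestor,
    default_length_plan,
    default_study_config,
    evolve,
    simulate_codon_gene,
    simulate_study,
)


SMALL_TREE = "((a:0.01,b:0.01):0.005,(c:0.01,d:0.012):0.005);"


def _small_config(**kw):
    cfg = EvolutionConfig(tree=SMALL_TREE, selection_genes=[], ndh_loss_events=[])
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def test_ancestor_ir_is_exact_reverse_complement(ancestor_pair):
    anc, _ = ancestor_pair
    L, I, S = (default_length_plan()[k] for k in ("LSC", "IR", "SSC"))
    assert anc.sequence[L + I + S:] == revcomp(anc.sequence[L: L + I])
    assert len(anc) == L + 2 * I + S


def test_ancestor_region_ordering_matches_plastome_proportions():
    plan = default_length_plan()
    assert plan["LSC"] > plan["IR"] > plan["SSC"]


def test_ancestor_places_seven_ndh_genes_in_ssc(ancestor_pair):
    anc, truth = ancestor_pair
    L, I, S = (default_length_plan()[k] for k in ("LSC", "IR", "SSC"))
    in_ssc = [
        f.name
        for f in anc.features
        if f.name.startswith("ndh") and L + I <= f.start < L + I + S
    ]
    assert len(set(in_ssc)) == 7


def test_ancestor_ycf1_spans_ssc_ira_junction(ancestor_pair):
    anc, _ = ancestor_pair
    L, I, S = (default_length_plan()[k] for k in ("LSC", "IR", "SSC"))
    main = [f for f in anc.features if f.name == "ycf1" and f.kind == "CDS"]
    frag = [f for f in anc.features if f.name == "ycf1" and f.kind == "pseudogene"]
    assert main and frag
    assert main[0].start < L + I + S <= main[0].end  # crosses J_SA
    assert frag[0].end == L + I                      # flush with J_SB


def test_same_seed_gives_identical_output():
    a1, r1, t1 = simulate_study(seed=11)
    a2, r2, t2 = simulate_study(seed=11)
    assert a1.sequence == a2.sequence
    for x, y in zip(r1, r2):
        assert x.id == y.id and x.sequence == y.sequence
    assert t1.alignment() == t2.alignment()


def test_all_rates_zero_leaves_identical_to_ancestor(ancestor_pair):
    anc, truth = ancestor_pair
    cfg = _small_config(
        region_rates={"CDS": 0.0, "intron": 0.0, "IGS": 0.0},
        indel_rate=0.0,
        ssr_slippage_rate=0.0,
    )
    records, tl = evolve(anc, cfg, truth)
    for rec in records:
        assert rec.sequence == anc.sequence
    assert tl.substitutions == []
    assert tl.indel_events == []


def test_degapped_truth_alignment_reproduces_leaves(study):
    _, records, truth = study
    aln = truth.alignment()
    for rec in records:
        assert aln[rec.id].replace("-", "") == rec.sequence


def test_leaf_irs_stay_mirrored(study):
    """Substitution mirroring keeps IRa == revcomp(IRb) on every leaf."""
    from plastocomp.structure import detect_inverted_repeat

    _, records, _ = study
    for rec in records[:3]:
        part = detect_inverted_repeat(rec, min_len=2000, max_mismatch_frac=0.0)
        n = len(rec)

        def span(iv):
            s, e = iv
            return rec.sequence[s:e] if s < e else rec.sequence[s:] + rec.sequence[:e]

        assert span(part.IRa) == revcomp(span(part.IRb))
        assert part.region_length("IRb") >= 5400  # planted IR never shrinks


def test_ndh_deletion_shrinks_ssc_by_deleted_span(ancestor_pair):
    anc, truth = ancestor_pair
    cfg = _small_config(
        region_rates={"CDS": 0.0, "intron": 0.0, "IGS": 0.0},
        indel_rate=0.0,
        ssr_slippage_rate=0.0,
        ndh_loss_events=[("a", "ndhG", "delete"), ("a", "ndhE", "delete")],
    )
    records, tl = evolve(anc, cfg, truth)
    byid = {r.id: r for r in records}
    span = sum(
        truth.gene_spans[g][1] - truth.gene_spans[g][0] for g in ("ndhG", "ndhE")
    )
    assert len(byid["a"]) == len(anc) - span
    assert len(byid["b"]) == len(anc)
    assert not byid["a"].features_named("ndhG")


def test_ndh_event_on_unknown_branch_or_gene_rejected(ancestor_pair):
    anc, truth = ancestor_pair
    with pytest.raises(ConfigError):
        evolve(anc, _small_config(ndh_loss_events=[("zzz", "ndhG", "delete")]), truth)
    with pytest.raises(ConfigError):
        evolve(anc, _small_config(ndh_loss_events=[("a", "nope", "delete")]), truth)


def test_igs_rate_multiplier_orders_realized_counts(ancestor_pair):
    """IGS multiplier 2x CDS: realized IGS density exceeds CDS density in
    a clear majority of seeds (sign test)."""
    anc, truth = ancestor_pair
    cls = truth.cls
    n_igs = int((cls == 0).sum())
    n_cds = int((cls == 2).sum())
    wins = 0
    n_seeds = 8
    for seed in range(n_seeds):
        cfg = _small_config(
            region_rates={"CDS": 1.0, "intron": 1.0, "IGS": 2.0},
            indel_rate=0.0, ssr_slippage_rate=0.0, seed=seed,
        )
        _, tl = evolve(anc, cfg, truth)
        igs = cds = 0
        for _, key in tl.substitutions:
            c = cls[int(key)] if key.denominator == 1 and int(key) < len(cls) else 0
            if c == 0:
                igs += 1
            elif c == 2:
                cds += 1
        wins += (igs / n_igs) > (cds / n_cds)
    assert wins >= n_seeds - 1


def test_realized_substitutions_near_poisson_expectation(ancestor_pair):
    anc, truth = ancestor_pair
    cfg = _small_config(indel_rate=0.0, ssr_slippage_rate=0.0, seed=5)
    _, tl = evolve(anc, cfg, truth)
    # tree length of the small tree
    T = 0.01 + 0.01 + 0.005 + 0.01 + 0.012 + 0.005
    # sampled sites exclude the IRa mirror copies and selection genes
    cls = truth.cls
    mirror_second = {b for a, b in truth.mirror.items() if b > a}
    counts = {0: 0, 1: 0, 2: 0}
    for p in range(len(cls)):
        if p in mirror_second:
            continue
        if cls[p] in counts:
            counts[cls[p]] += 1
    mult = {0: 1.45, 1: 1.0, 2: 0.72}
    expected = sum(mult[c] * counts[c] for c in counts) * T
    got = len(tl.substitutions)
    assert abs(got - expected) <= 4 * np.sqrt(expected)


def test_planted_repeats_recoverable_from_truth(ancestor_pair):
    anc, truth = ancestor_pair
    cfg = _small_config(
        region_rates={"CDS": 0.0, "intron": 0.0, "IGS": 0.0},
        indel_rate=0.0, ssr_slippage_rate=0.0,
        planted_repeats=[("forward", 40, 2), ("palindromic", 36, 0)],
    )
    records, tl = evolve(anc, cfg, truth)
    assert len(tl.planted_repeats) == 2
    rec = records[0]
    for pr in tl.planted_repeats:
        (s1, e1), (s2, e2) = pr["pos1"], pr["pos2"]
        a = rec.sequence[s1:e1]
        b = rec.sequence[s2:e2]
        if pr["class"] == "forward":
            b2 = b
        elif pr["class"] == "reverse":
            b2 = b[::-1]
        else:
            b2 = revcomp(b)
        assert sum(x != y for x, y in zip(a, b2)) == pr["mismatches"]


def test_planted_ssrs_recoverable_on_leaves(study):
    from plastocomp.repeats import scan_ssrs

    from plastocomp.repeats import canonical_motif

    _, records, truth = study
    for rec in records[:3]:
        loci = {(l.motif, l.count) for l in scan_ssrs(rec.sequence)}
        for li, count in truth.ssr_truth[rec.id].items():
            motif = canonical_motif(truth.planted_ssrs[li]["motif"])
            if count >= {1: 10, 2: 5}.get(len(motif), 3):
                assert any(
                    m == motif and c >= count for m, c in loci
                ), (rec.id, motif, count, sorted(loci))


def test_simulate_codon_gene_basics():
    aln, classes = simulate_codon_gene(SMALL_TREE, (1.0, 0.5, 1.5, 1.0, 2.0), 40, seed=1)
    # p0 = 1: no site in the positive class
    assert (classes == 10).sum() == 0
    zero_tree = "((a:0,b:0):0,(c:0,d:0):0);"
    aln0, _ = simulate_codon_gene(zero_tree, (0.9, 0.5, 1.5, 2.0, 2.0), 30, seed=2)
    assert len(set(aln0.values())) == 1
    with pytest.raises(ValueError):
        simulate_codon_gene(SMALL_TREE, (0.9, 0.5, 1.5, 0.5, 2.0), 30)


def test_positive_site_count_is_binomial():
    counts = []
    for seed in range(10):
        _, classes = simulate_codon_gene(
            SMALL_TREE, (0.9, 0.5, 1.5, 3.0, 2.0), 300, seed=seed
        )
        counts.append(int((classes == 10).sum()))
    mean = np.mean(counts)
    # binomial(300, 0.1): mean 30, sd ~5.2; the mean of 10 draws is tight
    assert abs(mean - 30) < 3 * 5.2 / np.sqrt(10)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        _small_config(indel_length=0.0).validate()
    with pytest.raises(ConfigError):
        _small_config(indel_rate=-1.0).validate()
    with pytest.raises(ConfigError):
        _small_config(ndh_loss_events=[("a", "ndhG", "explode")]).validate()
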