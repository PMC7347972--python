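import itertools
import math

import numpy as np
import pytest
from scipy import stats as sstats

from plastocomp._codon import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from plastocomp.codonmodel import (
    CodonModel,
    OmegaMixture,
    beta_category_means,
    brute_force_loglikelihood,
    encode_codon_alignment,
    mixture_loglikelihood,
    plastid_like_frequencies,
    pruning_site_likelihoods,
)
from plastocomp.selection import (
    build_codon_alignment,
    fit_codon_model,
    gene_divergence,
    k2p_distance,
    lrt_m8_vs_m8a,
    ng86_dnds,
    nj_tree,
    site_posteriors,
)
from plastocomp.synthetic import simulate_codon_gene
from plastocomp.trees import parse_newick


def _leaf_codons(aln):
    names, mat = encode_codon_alignment(aln)
    return {n: mat[i] for i, n in enumerate(names)}


# --- likelihood machinery --------------------------------------------------


@pytest.mark.parametrize(
    "newick,mix",
    [
        ("(A:0.1,B:0.25);", OmegaMixture.m0(0.4)),
        ("((A:0.1,B:0.2):0.05,C:0.15);", OmegaMixture.m8(0.8, 0.5, 1.5, 3.0, 3)),
        ("((A:0.1,B:0.2):0.05,C:0.15,D:0.3);", OmegaMixture.m8a(0.9, 0.4, 1.2, 3)),
    ],
)
def test_pruning_equals_exhaustive_summation(newick, mix):
    tree = parse_newick(newick)
    aln, _ = simulate_codon_gene(newick, (0.8, 0.5, 1.5, 2.0, 2.0), 25, seed=3)
    leaf = _leaf_codons(aln)
    model = CodonModel(2.0, mix, plastid_like_frequencies())
    assert abs(
        mixture_loglikelihood(tree, leaf, model)
        - brute_force_loglikelihood(tree, leaf, model)
    ) < 1e-8


def test_site_class_posteriors_sum_to_one():
    newick = "((A:0.1,B:0.2):0.05,C:0.15,D:0.3);"
    aln, _ = simulate_codon_gene(newick, (0.8, 0.5, 1.5, 2.5, 2.0), 60, seed=9)
    model = CodonModel(2.0, OmegaMixture.m8(0.8, 0.5, 1.5, 2.5, 10),
                       plastid_like_frequencies())
    tree = parse_newick(newick)
    lik, logscale = pruning_site_likelihoods(tree, _leaf_codons(aln), model)
    w = model.mixture.weights[:, None]
    m = logscale.max(axis=0)
    weighted = w * lik * np.exp(logscale - m[None, :])
    post = weighted / weighted.sum(axis=0, keepdims=True)
    assert np.allclose(post.sum(axis=0), 1.0)


def test_beta_discretization_means_average_to_distribution_mean():
    p, q = 0.7, 2.1
    means = beta_category_means(p, q, 10)
    assert means.mean() == pytest.approx(p / (p + q), rel=1e-6)
    assert (np.diff(means) > 0).all()


def test_identical_sequences_fit_zero_branches_and_pi_loglik():
    cds = "ATGAAATTTCCCGGGAAATTATGA".replace("TGA", "GGA")  # no stops
    cds = cds[: len(cds) - len(cds) % 3]
    aln = {"A": cds, "B": cds}
    fit = fit_codon_model(aln, "(A:0.01,B:0.01);", "M0")
    assert sum(fit.tree.branch_lengths()) < 1e-5
    leaf = _leaf_codons(aln)
    expected = sum(math.log(fit.pi[c]) for c in leaf["A"])
    assert fit.lnl == pytest.approx(expected, abs=1e-4)


# --- LRT -------------------------------------------------------------------


def test_lrt_identical_fits_is_zero_with_p_one():
    newick = "((A:0.1,B:0.2):0.05,C:0.15,D:0.3);"
    aln, _ = simulate_codon_gene(newick, (1.0, 0.5, 1.5, 1.0, 2.0), 40, seed=4)
    m0 = fit_codon_model(aln, newick, "M0", optimize_branches=False)
    m8a = fit_codon_model(aln, newick, "M8a", 4, base_fit=m0)
    stat, p = lrt_m8_vs_m8a(m8a, m8a.__class__(**{**m8a.__dict__, "model": "M8"}))
    assert stat == 0.0
    assert p == 1.0


def test_lrt_rejects_under_strong_selection():
    newick = "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,(e:0.1,f:0.1):0.05);"
    aln, _ = simulate_codon_gene(newick, (0.7, 0.5, 1.5, 5.0, 2.0), 250, seed=21)
    m0 = fit_codon_model(aln, newick, "M0", optimize_branches=False)
    m8a = fit_codon_model(aln, newick, "M8a", 5, base_fit=m0)
    m8 = fit_codon_model(aln, newick, "M8", 5, base_fit=m0, null_fit=m8a)
    stat, p = lrt_m8_vs_m8a(m8a, m8)
    assert m8.lnl >= m8a.lnl
    assert p < 0.01
    sites = site_posteriors(m8, aln, lrt_p=p)
    assert len(sites.positive_sites) > 0
    # flagged sites have posterior mean omega > 1
    for s in sites.positive_sites:
        assert sites.posterior_mean_omega[s] > 1.0


def test_no_positive_calls_on_identical_alignment():
    cds = "ATGAAATTTCCCGGGAAATTA"
    aln = {"A": cds, "B": cds, "C": cds}
    m0 = fit_codon_model(aln, "(A:0.01,B:0.01,C:0.01);", "M0", optimize_branches=False)
    m8a = fit_codon_model(aln, "(A:0.01,B:0.01,C:0.01);", "M8a", 4, base_fit=m0)
    m8 = fit_codon_model(aln, "(A:0.01,B:0.01,C:0.01);", "M8", 4, base_fit=m0, null_fit=m8a)
    _, p = lrt_m8_vs_m8a(m8a, m8)
    sites = site_posteriors(m8, aln, lrt_p=p)
    assert sites.positive_sites == []


# --- NJ --------------------------------------------------------------------


def test_nj_three_taxa_solves_three_point_equations():
    rng = np.random.default_rng(0)
    base = "".join(rng.choice(list("ACGT"), size=600))

    def mutate(s, k, seed):
        r = np.random.default_rng(seed)
        s = list(s)
        for p in r.choice(len(s), size=k, replace=False):
            s[p] = "ACGT"[("ACGT".index(s[p]) + 2) % 4]
        return "".join(s)

    aln = {"A": base, "B": mutate(base, 30, 1), "C": mutate(base, 60, 2)}
    nwk = nj_tree(aln)
    t = parse_newick(nwk)
    d = {
        (x, y): k2p_distance(aln[x], aln[y])
        for x, y in itertools.combinations("ABC", 2)
    }
    # three-point closed form: b_X = (dXY + dXZ - dYZ)/2, clamped at zero
    lengths = {n.name: n.length for n in t.nodes if n.is_leaf}

    def closed(x, y, z):
        def dd(u, v):
            return d.get((u, v), d.get((v, u)))

        return max(0.0, (dd(x, y) + dd(x, z) - dd(y, z)) / 2)

    for x, y, z in (("A", "B", "C"), ("B", "A", "C"), ("C", "A", "B")):
        assert lengths[x] == pytest.approx(closed(x, y, z), abs=1e-10)


def test_nj_recovers_additive_four_taxon_tree():
    # additive distances from ((A:1,B:2):1,(C:3,D:4):1) scaled by 0.01
    true = {
        ("A", "B"): 3, ("A", "C"): 6, ("A", "D"): 7,
        ("B", "C"): 7, ("B", "D"): 8, ("C", "D"): 7,
    }
    import skbio

    names = ["A", "B", "C", "D"]
    dm = np.zeros((4, 4))
    for (x, y), v in true.items():
        i, j = names.index(x), names.index(y)
        dm[i, j] = dm[j, i] = v * 0.01
    tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names))
    # A and B are siblings on the recovered topology
    tips = {t.name for t in tree.find("A").parent.tips()}
    assert tips == {"A", "B"} or tips == {"C", "D"}


def test_identical_sequences_give_zero_branch_star():
    aln = {x: "ATGAAATTT" for x in "ABCD"}
    t = parse_newick(nj_tree(aln))
    assert sum(t.branch_lengths()) == 0.0


# --- divergence & alignment assembly ---------------------------------------


def test_gene_divergence_is_mean_branch_length():
    newick = "((A:0.1,B:0.2):0.05,C:0.15,D:0.3);"
    aln, _ = simulate_codon_gene(newick, (1.0, 0.5, 1.5, 1.0, 2.0), 50, seed=2)
    fit = fit_codon_model(aln, newick, "M0", optimize_branches=False)
    b = fit.tree.branch_lengths()
    assert gene_divergence(fit) == pytest.approx(sum(b) / len(b))
    star = parse_newick("(A:0,B:0,C:0);")
    fitlike = type(fit)(model="M0", lnl=0.0, kappa=2.0, pi=fit.pi, tree=star)
    assert gene_divergence(fitlike) == 0.0


def test_build_codon_alignment_drops_gap_and_stop_columns():
    aln = {"A": "ATGAAATTT", "B": "ATG---TTT", "C": "ATGAAATTT"}
    out, removed = build_codon_alignment(aln)
    assert removed == 1
    assert out["A"] == "ATGTTT"
    ident = {"A": "ATGAAA", "B": "ATGAAA"}
    out, removed = build_codon_alignment(ident)
    assert removed == 0 and out == ident


# --- NG86 ------------------------------------------------------------------


def test_ng86_trivial_cases():
    dn, ds, w = ng86_dnds("ATGAAA", "ATGAAA")
    assert dn == 0.0 and ds == 0.0
    # one synonymous difference across several codons
    dn, ds, w = ng86_dnds("TTTAAAGGGCCC", "TTCAAAGGGCCC")
    assert dn == 0.0 and ds > 0.0 and np.isfinite(ds) and w == 0.0


def _ng86_codon_oracle(a, b):
    """Independent pathway enumeration for a single codon pair."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    return results


@pytest.mark.parametrize("seed", range(10))
def test_ng86_pathway_counts_match_enumeration(seed):
    rng = np.random.default_rng(seed)
    codons = [c for c in SENSE_CODONS]
    a = codons[rng.integers(len(codons))]
    b = codons[rng.integers(len(codons))]
    from plastocomp.selection import _path_changes

    paths = _ng86_codon_oracle(a, b)
    if paths:
        sd = sum(x for x, _ in paths) / len(paths)
        nd = sum(y for _, y in paths) / len(paths)
        got_sd, got_nd = _path_changes(a, b)
        assert (got_sd, got_nd) == pytest.approx((sd, nd))


def test_ng86_site_counts_partition_three_sites():
    from plastocomp.selection import _codon_sites

    for codon in ("TTT", "ATG", "CTG", "GGG"):
        s, n = _codon_sites(codon)
        assert s + n == pytest.approx(3.0)


def test_m0_omega_tracks_ng86_across_genes():
    """Fitted M0 omega correlates with NG86 pairwise omega (rank >= 0.8)."""
    newick = "(A:0.15,B:0.15,C:0.15);"
    omegas = [0.05, 0.15, 0.4, 0.8, 1.5, 3.0]
    fitted, counted = [], []
    for i, w in enumerate(omegas):
        aln, _ = simulate_codon_gene(
            newick, (1e-9, 0.5, 1.5, max(w, 1.0), 2.0) if w >= 1 else (1.0 - 1e-9, 1.0, (1 - w) / w, 1.0, 2.0),
            220, seed=40 + i,
        )
        # simulate near a point mass at omega: p0~0 puts all mass on omega_s
        fit = fit_codon_model(aln, newick, "M0", optimize_branches=False)
        fitted.append(fit.omega)
        dn, ds, om = ng86_dnds(aln["A"], aln["B"])
        counted.append(om if np.isfinite(om) else 10.0)
    rho = sstats.spearmanr(fitted, counted).statistic
    assert rho >= 0.8
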