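"""Site-model selection scan: M0 / M8a / M8 fits, the M8-vs-M8a
likelihood-ratio test, and naive empirical-Bayes site posteriors.

Likelihoods use the GY94 machinery in :mod:`plastocomp.codonmodel` over
a fixed tree topology.  Optimization is two-stage: M0 maximizes lnL
over kappa, omega and all branch lengths; M8a and M8 then maximize
their mixture parameters, kappa and a single branch-scale factor on the
M0 branch lengths.  The null and alternative receive the same
treatment, and M8 is warm-started at the M8a optimum (with omega_s at
its boundary), so lnL(M8) >= lnL(M8a) at the reported optima.
The LRT statistic 2*(lnL_M8 - lnL_M8a), clamped at zero, is referred to
chi-square with 1 df — conservative relative to the 50:50 mixture.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._codon import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_transition, revcomp
from .codonmodel import (
    CodonModel,
    OmegaMixture,
    encode_codon_alignment,
    f3x4_frequencies,
    mixture_loglikelihood,
    pruning_site_likelihoods,
)
from .trees import Tree, parse_newick


# ---------------------------------------------------------------------------
# codon alignment assembly


def build_codon_alignment(
    aligned_nt: dict[str, str],
) -> tuple[dict[str, str], int]:
    """Reduce an in-frame nucleotide alignment to clean codon columns.

    Codon columns containing a gap, an N, or a stop codon in any
    sequence are removed; returns (codon alignment, removed count).
    """
    ncol = len(next(iter(aligned_nt.values())))
    if ncol % 3:
        raise ValueError("aligned length not divisible by 3")
    keep = []
    removed = 0
    for j in range(ncol // 3):
        ok = True
        for s in aligned_nt.values():
            codon = s[3 * j : 3 * j + 3].upper()
            if "-" in codon or "N" in codon or codon in STOP_CODONS:
                ok = False
                break
        if ok:
            keep.append(j)
        else:
            removed += 1
    out = {
        name: "".join(s[3 * j : 3 * j + 3] for j in keep)
        for name, s in aligned_nt.items()
    }
    return out, removed


# ---------------------------------------------------------------------------
# K2P distances and neighbor joining


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance; falls back to p-distance when the
    log arguments are non-positive (saturation)."""
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        return 0.0
    n = len(pairs)
    ts = sum(1 for x, y in pairs if x != y and is_transition(x, y)) / n
    tv = sum(1 for x, y in pairs if x != y and not is_transition(x, y)) / n
    arg1 = 1 - 2 * ts - tv
    arg2 = 1 - 2 * tv
    if arg1 <= 0 or arg2 <= 0:
        return ts + tv  # p-distance fallback
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def nj_tree(alignment: dict[str, str]) -> str:
    """Neighbor-joining newick from K2P distances.

    Negative branch lengths are clamped to zero; taxon order fixes
    tie-breaking.  Three taxa give the unique unrooted topology with
    branch lengths solving the three-point equations.
    """
    import skbio

    names = list(alignment)
    if len(names) < 3:
        raise ValueError("need >= 3 sequences")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(alignment[names[i]], alignment[names[j]])
            dm[i, j] = dm[j, i] = d
    tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# ---------------------------------------------------------------------------
# model fits


@dataclass
class CodonModelFit:
    """One fitted codon model on a fixed topology."""

    model: str
    lnl: float
    kappa: float
    pi: np.ndarray = field(repr=False)
    tree: Tree = field(repr=False)
    omega: float | None = None          # M0
    p0: float | None = None
    p: float | None = None
    q: float | None = None
    omega_s: float | None = None
    ncat: int = 10
    converged: bool = True

    def mixture(self) -> OmegaMixture:
        if self.model == "M0":
            return OmegaMixture.m0(self.omega)
        return OmegaMixture.m8(self.p0, self.p, self.q, self.omega_s, self.ncat)


def _prepare(alignment, tree):
    names, mat = encode_codon_alignment(alignment)
    counts = np.zeros(len(SENSE_CODONS))
    vals, cnts = np.unique(mat[mat >= 0], return_counts=True)
    counts[vals] = cnts
    pi = f3x4_frequencies(counts)
    t = parse_newick(tree) if isinstance(tree, str) else tree
    if set(t.leaf_names) != set(names):
        raise ValueError("tree leaves do not match alignment names")
    leaf_codons = {name: mat[i] for i, name in enumerate(names)}
    return leaf_codons, pi, t


def fit_codon_model(
    alignment: dict[str, str],
    tree: str | Tree,
    model: str = "M8",
    n_beta_categories: int = 10,
    base_fit: CodonModelFit | None = None,
    optimize_branches: bool = True,
    null_fit: CodonModelFit | None = None,
) -> CodonModelFit:
    """Maximum-likelihood fit of M0, M8a or M8 on a fixed topology.

    With ``optimize_branches=False`` the M0 stage optimizes a single
    scale factor on the supplied branch lengths instead of every branch
    — much faster, adequate when the topology and relative lengths come
    from a trusted source (the simulator's tree, or an NJ estimate).
    """
    if model not in ("M0", "M8a", "M8"):
        raise ValueError(f"unknown model {model!r}")
    leaf_codons, pi, t = _prepare(alignment, tree)
    if model == "M0":
        return _fit_m0(leaf_codons, pi, t, optimize_branches)
    if base_fit is None or base_fit.model != "M0":
        base_fit = _fit_m0(leaf_codons, pi, t, optimize_branches)
    if model == "M8a":
        return _fit_m8(leaf_codons, pi, base_fit, n_beta_categories, fix_omega_s=True)
    if null_fit is None or null_fit.model != "M8a":
        null_fit = _fit_m8(leaf_codons, pi, base_fit, n_beta_categories, fix_omega_s=True)
    return _fit_m8(
        leaf_codons, pi, base_fit, n_beta_categories, fix_omega_s=False,
        null_fit=null_fit,
    )


def _fit_m0(leaf_codons, pi, t: Tree, optimize_branches: bool = True) -> CodonModelFit:
    nb = len(t.nodes) - 1
    b0 = np.maximum(np.array(t.branch_lengths(), dtype=float) * 3.0, 1e-4)

    if optimize_branches:
        def nll(x):
            t.set_branch_lengths(x[2:])
            model = CodonModel(x[0], OmegaMixture.m0(x[1]), pi)
            return -mixture_loglikelihood(t, leaf_codons, model)

        x0 = np.concatenate([[2.0, 0.2], b0])
        bounds = [(0.1, 99.0), (1e-4, 20.0)] + [(1e-7, 8.0)] * nb
    else:
        def nll(x):
            t.set_branch_lengths(b0 * x[2])
            model = CodonModel(x[0], OmegaMixture.m0(x[1]), pi)
            return -mixture_loglikelihood(t, leaf_codons, model)

        x0 = np.array([2.0, 0.2, 1.0])
        bounds = [(0.1, 99.0), (1e-4, 20.0), (0.02, 50.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-8},
    )
    if optimize_branches:
        t.set_branch_lengths(res.x[2:])
    else:
        t.set_branch_lengths(b0 * res.x[2])
    return CodonModelFit(
        model="M0", lnl=-res.fun, kappa=float(res.x[0]), omega=float(res.x[1]),
        pi=pi, tree=t, converged=bool(res.success),
    )


def _fit_m8(
    leaf_codons, pi, base: CodonModelFit, ncat: int,
    fix_omega_s: bool, null_fit: CodonModelFit | None = None,
) -> CodonModelFit:
    base_b = np.array(base.tree.branch_lengths(), dtype=float)
    t = parse_newick(base.tree.to_newick())  # private copy; fits keep their own tree

    def unpack(x):
        kappa, scale, p0, p, q = x[:5]
        omega_s = 1.0 if fix_omega_s else x[5]
        return kappa, scale, p0, p, q, omega_s

    def nll(x):
        kappa, scale, p0, p, q, omega_s = unpack(x)
        t.set_branch_lengths(base_b * scale)
        mix = OmegaMixture.m8(p0, p, q, omega_s, ncat)
        model = CodonModel(kappa, mix, pi)
        return -mixture_loglikelihood(t, leaf_codons, model)

    bounds = [(0.5, 30.0), (0.05, 20.0), (0.005, 1 - 1e-4), (0.05, 20.0), (0.05, 20.0)]
    if not fix_omega_s:
        bounds.append((1.0, 30.0))
    starts = []
    if null_fit is not None:
        # warm start at the null optimum: omega_s at its boundary leaves the
        # likelihood unchanged, so the optimum can only improve on the null
        s0 = [null_fit.kappa, 1.0, null_fit.p0, null_fit.p, null_fit.q]
        scale_null = np.array(null_fit.tree.branch_lengths()).sum() / max(
            base_b.sum(), 1e-9
        )
        s0[1] = scale_null
        starts.append(s0 + [2.0])
    else:
        mean_w = min(max(base.omega or 0.2, 1e-3), 0.95)
        p_init = 0.5
        q_init = p_init * (1 - mean_w) / max(mean_w, 1e-3)
        s0 = [base.kappa, 1.0, 0.9, p_init, min(q_init, 20.0)]
        starts.append(s0 if fix_omega_s else s0 + [2.0])
        starts.append([base.kappa, 1.0, 0.99, 0.3, 3.0] + ([] if fix_omega_s else [1.5]))
    best = None
    for x0 in starts:
        x0 = np.clip(
            np.array(x0, dtype=float), [b[0] for b in bounds], [b[1] for b in bounds]
        )
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 80, "ftol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, scale, p0, p, q, omega_s = unpack(best.x)
    t.set_branch_lengths(base_b * scale)
    lnl = -best.fun
    if null_fit is not None and lnl < null_fit.lnl:
        # numerical guard: the nested null can never beat the alternative
        kappa, p0, p, q = null_fit.kappa, null_fit.p0, null_fit.p, null_fit.q
        omega_s, lnl = 1.0, null_fit.lnl
    return CodonModelFit(
        model="M8a" if fix_omega_s else "M8",
        lnl=lnl, kappa=float(kappa), pi=pi, tree=t,
        p0=float(p0), p=float(p), q=float(q), omega_s=float(omega_s),
        ncat=ncat, converged=bool(best.success),
    )


def lrt_m8_vs_m8a(
    fit_null: CodonModelFit, fit_alt: CodonModelFit
) -> tuple[float, float]:
    """2*(lnL_M8 - lnL_M8a) clamped at 0; p from chi-square, 1 df."""
    if fit_null.model != "M8a" or fit_alt.model != "M8":
        raise ValueError("expected an M8a null and an M8 alternative")
    stat = max(0.0, 2.0 * (fit_alt.lnl - fit_null.lnl))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# site posteriors


@dataclass
class SiteSelection:
    """Naive empirical-Bayes site classification under the M8 fit."""

    posterior_positive: np.ndarray   # P(omega_s class | data) per site
    posterior_mean_omega: np.ndarray
    positive_sites: list[int]        # 0-based flagged sites
    cutoff: float


def site_posteriors(
    fit_alt: CodonModelFit,
    alignment: dict[str, str],
    tree: str | Tree | None = None,
    lrt_p: float | None = None,
    cutoff: float = 0.95,
    alpha: float = 0.05,
) -> SiteSelection:
    """Per-site class posteriors at the MLEs; a site is flagged positive
    when the LRT is significant (if supplied), the omega_s-class
    posterior reaches ``cutoff``, and the posterior mean omega > 1."""
    t = fit_alt.tree if tree is None else (parse_newick(tree) if isinstance(tree, str) else tree)
    leaf_codons, _, _ = _prepare(alignment, t)
    mix = fit_alt.mixture()
    model = CodonModel(fit_alt.kappa, mix, fit_alt.pi)
    lik, logscale = pruning_site_likelihoods(t, leaf_codons, model)
    m = logscale.max(axis=0)
    weighted = mix.weights[:, None] * lik * np.exp(logscale - m[None, :])
    post = weighted / np.maximum(weighted.sum(axis=0, keepdims=True), 1e-300)
    post_pos = post[-1]
    mean_omega = (post * mix.omegas[:, None]).sum(axis=0)
    significant = lrt_p is None or lrt_p < alpha
    flagged = [
        int(i)
        for i in np.nonzero((post_pos >= cutoff) & (mean_omega > 1.0))[0]
        if significant
    ]
    return SiteSelection(post_pos, mean_omega, flagged, cutoff)


def gene_divergence(fit: CodonModelFit) -> float:
    """Average branch length of the fitted gene tree."""
    b = fit.tree.branch_lengths()
    return float(sum(b) / len(b)) if b else 0.0


# ---------------------------------------------------------------------------
# whole-gene scan


@dataclass
class GeneScanResult:
    gene: str
    m0: CodonModelFit
    m8a: CodonModelFit
    m8: CodonModelFit
    lrt_stat: float
    lrt_p: float
    sites: SiteSelection

    @property
    def n_positive(self) -> int:
        return len(self.sites.positive_sites)

    @property
    def mean_branch_length(self) -> float:
        return gene_divergence(self.m0)


def scan_gene(
    gene: str,
    alignment: dict[str, str],
    tree: str | Tree | None = None,
    n_beta_categories: int = 10,
    optimize_branches: bool = True,
) -> GeneScanResult:
    """Fit M0/M8a/M8, test M8 vs M8a and call positive sites."""
    if tree is None:
        tree = nj_tree(alignment)
    m0 = fit_codon_model(alignment, tree, "M0", optimize_branches=optimize_branches)
    m8a = fit_codon_model(alignment, tree, "M8a", n_beta_categories, base_fit=m0)
    leaf_codons, pi, t = _prepare(alignment, m0.tree)
    m8 = _fit_m8(leaf_codons, pi, m0, n_beta_categories, fix_omega_s=False, null_fit=m8a)
    stat, p = lrt_m8_vs_m8a(m8a, m8)
    sites = site_posteriors(m8, alignment, lrt_p=p)
    return GeneScanResult(gene, m0, m8a, m8, stat, p, sites)


# ---------------------------------------------------------------------------
# NG86 counting (independent of the ML machinery)

_NT = "ACGT"


def _codon_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous / nonsynonymous site counts of one codon."""
    syn = 0.0
    for pos in range(3):
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def _path_changes(a: str, b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over all mutational
    orderings between two codons, skipping paths through stops."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all paths blocked by stops: fall back to including them
        for order in itertools.permutations(diffs):
            cur = a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                aa_next = GENETIC_CODE[nxt]
                if aa_next == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_dnds(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Nei-Gojobori (1986) dN, dS and omega with Jukes-Cantor correction.

    Saturated distances (log argument <= 0) come back as inf.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("stop codon in sequence")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _path_changes(ca, cb)
        Sd += sd
        Nd += nd

    def jc(pdist: float) -> float:
        arg = 1 - 4 * pdist / 3
        if arg <= 0:
            return float("inf")
        return -0.75 * math.log(arg)

    ds = jc(Sd / S) if S > 0 else 0.0
    dn = jc(Nd / N) if N > 0 else 0.0
    if ds == 0.0:
        omega = float("inf") if dn > 0 else float("nan")
    elif math.isinf(ds):
        omega = float("nan")
    else:
        omega = dn / ds
    return dn, ds, omega
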