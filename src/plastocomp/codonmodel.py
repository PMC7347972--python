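"""GY94-style codon substitution machinery: rate matrices, the M-series
site mixtures (M0, M8a, M8), and the pruning log-likelihood.

The instantaneous rate from codon i to j is zero unless they differ at
exactly one position; otherwise q_ij = pi_j * (kappa if the change is a
transition) * (omega if it is nonsynonymous).  Site-to-site variation
enters through a mixture over omega classes: M8 draws omega from a
discretized Beta(p, q) (equal-probability categories, category-mean
representatives) with probability p0 and from a point mass omega_s >= 1
with probability 1 - p0; M8a fixes omega_s = 1.  Branch lengths are in
expected substitutions per codon under the mixture-averaged rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._codon import GENETIC_CODE, SENSE_CODONS, SENSE_INDEX, is_transition
from .trees import Tree

NCODON = len(SENSE_CODONS)  # 61

# static change tables -------------------------------------------------------
_DIFF = np.zeros((NCODON, NCODON), dtype=np.int8)      # n differing positions
_TS = np.zeros((NCODON, NCODON), dtype=bool)           # single-pos transition
_NONSYN = np.zeros((NCODON, NCODON), dtype=bool)
for _i, _a in enumerate(SENSE_CODONS):
    for _j, _b in enumerate(SENSE_CODONS):
        diffs = [(x, y) for x, y in zip(_a, _b) if x != y]
        _DIFF[_i, _j] = len(diffs)
        if len(diffs) == 1:
            _TS[_i, _j] = is_transition(*diffs[0])
            _NONSYN[_i, _j] = GENETIC_CODE[_a] != GENETIC_CODE[_b]
_SINGLE = _DIFF == 1


def f3x4_frequencies(codon_counts: np.ndarray | dict[str, int]) -> np.ndarray:
    """F3x4 codon frequencies from observed counts, renormalized over the
    61 sense codons with a small floor against empty cells."""
    pos_freq = np.zeros((3, 4))
    order = "TCAG"
    if isinstance(codon_counts, dict):
        counts = np.zeros(NCODON)
        for c, n in codon_counts.items():
            if c in SENSE_INDEX:
                counts[SENSE_INDEX[c]] = n
    else:
        counts = np.asarray(codon_counts, dtype=float)
    for idx, codon in enumerate(SENSE_CODONS):
        for pos, ch in enumerate(codon):
            pos_freq[pos, order.index(ch)] += counts[idx]
    pos_freq += 1e-6
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, order.index(c[0])]
            * pos_freq[1, order.index(c[1])]
            * pos_freq[2, order.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def plastid_like_frequencies(at: float = 0.64) -> np.ndarray:
    """AT-rich F3x4-style default frequencies for simulation."""
    nt = {"A": at / 2, "T": at / 2, "C": (1 - at) / 2, "G": (1 - at) / 2}
    pi = np.array([nt[c[0]] * nt[c[1]] * nt[c[2]] for c in SENSE_CODONS])
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94 rate matrix for one omega class."""
    Q = np.where(_SINGLE, np.where(_TS, kappa, 1.0), 0.0)
    Q = Q * np.where(_NONSYN, omega, 1.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def beta_category_means(p: float, q: float, ncat: int) -> np.ndarray:
    """Equal-probability discretization of Beta(p, q); category means."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    edges = stats.beta.ppf(np.linspace(0, 1, ncat + 1), p, q)
    upper = stats.beta.cdf(edges, p + 1, q)
    means = ncat * (p / (p + q)) * np.diff(upper)
    return np.clip(means, 1e-8, 1.0)


@dataclass(frozen=True)
class OmegaMixture:
    """Site-class mixture: omega values and their prior weights."""

    omegas: np.ndarray
    weights: np.ndarray

    @staticmethod
    def m0(omega: float) -> "OmegaMixture":
        return OmegaMixture(np.array([omega]), np.array([1.0]))

    @staticmethod
    def m8(
        p0: float, p: float, q: float, omega_s: float, ncat: int = 10
    ) -> "OmegaMixture":
        if not (0.0 <= p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if omega_s < 1.0:
            raise ValueError("omega_s must be >= 1")
        omegas = np.append(beta_category_means(p, q, ncat), omega_s)
        weights = np.append(np.full(ncat, p0 / ncat), 1.0 - p0)
        return OmegaMixture(omegas, weights)

    @staticmethod
    def m8a(p0: float, p: float, q: float, ncat: int = 10) -> "OmegaMixture":
        return OmegaMixture.m8(p0, p, q, 1.0, ncat)

    @property
    def positive_class(self) -> int:
        return len(self.omegas) - 1


_EIG_CACHE: dict[tuple, tuple] = {}


def _class_eig(kappa: float, omega: float, pi: np.ndarray, pi_token: int):
    """Eigendecomposition of the unnormalized class matrix, cached.

    The cache pays off during finite-difference gradients, which perturb
    one parameter at a time and so reuse most class matrices.
    """
    key = (pi_token, round(kappa, 14), round(omega, 14))
    hit = _EIG_CACHE.get(key)
    if hit is not None:
        return hit
    Q = rate_matrix(kappa, omega, pi)
    rate = float(-(pi * np.diag(Q)).sum())
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    left = V.T * sqrt_pi[None, :]        # V' D^{1/2}
    right = V / sqrt_pi[:, None]         # D^{-1/2} V
    out = (lam, right, left, rate, Q)
    if len(_EIG_CACHE) > 8192:
        _EIG_CACHE.clear()
    _EIG_CACHE[key] = out
    return out


class CodonModel:
    """Rate matrices + eigendecompositions for one parameter setting.

    Branch lengths are expected substitutions per codon averaged over
    the mixture, so all classes share one normalization factor (applied
    to the time argument; class matrices stay unnormalized and
    cacheable).
    """

    def __init__(self, kappa: float, mixture: OmegaMixture, pi: np.ndarray):
        self.kappa = float(kappa)
        self.mixture = mixture
        self.pi = np.asarray(pi, dtype=float)
        token = hash(self.pi.tobytes())
        self._eig = [
            _class_eig(self.kappa, float(w), self.pi, token) for w in mixture.omegas
        ]
        mean_rate = float(
            sum(w * e[3] for w, e in zip(mixture.weights, self._eig))
        )
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix")
        self.mean_rate = mean_rate

    @property
    def qs(self) -> list[np.ndarray]:
        return [e[4] / self.mean_rate for e in self._eig]

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t) per class, shape (nclass, 61, 61)."""
        t = max(float(t), 0.0) / self.mean_rate
        out = np.empty((len(self._eig), NCODON, NCODON))
        for c, (lam, right, left, _rate, _Q) in enumerate(self._eig):
            P = (right * np.exp(lam * t)[None, :]) @ left
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            out[c] = P
        return out


def encode_codon_alignment(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Codon strings -> integer matrix (taxa x sites); -1 for any codon
    containing a gap, N, or a stop."""
    names = list(seqs)
    nsites = len(next(iter(seqs.values()))) // 3
    mat = np.full((len(names), nsites), -1, dtype=np.int64)
    for r, name in enumerate(names):
        s = seqs[name].upper()
        for j in range(nsites):
            mat[r, j] = SENSE_INDEX.get(s[3 * j : 3 * j + 3], -1)
    return names, mat


def pruning_site_likelihoods(
    tree: Tree,
    leaf_codons: dict[str, np.ndarray],
    model: CodonModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class per-site likelihoods by Felsenstein pruning.

    Returns (lik, logscale), each of shape (nclass, nsites): the site
    likelihood for class c is lik[c, s] * exp(logscale[c, s]).
    """
    nclass = len(model.qs)
    nsites = len(next(iter(leaf_codons.values())))
    partials: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        if node.is_leaf:
            codes = leaf_codons[node.name]
            part = np.zeros((nclass, nsites, NCODON))
            known = codes >= 0
            part[:, known, codes[known]] = 1.0
            part[:, ~known, :] = 1.0
            scale = np.zeros((nclass, nsites))
        else:
            part = np.ones((nclass, nsites, NCODON))
            scale = np.zeros((nclass, nsites))
            for ch in node.children:
                P = model.transition_matrices(ch.length)
                # (c,s,j) x (c,i,j)^T -> (c,s,i), batched over classes
                down = partials.pop(ch.index) @ P.transpose(0, 2, 1)
                part *= down
                scale += logscale.pop(ch.index)
                if part.max() < 1e-220:  # rescale only when underflow nears
                    m = part.max(axis=2)
                    m[m == 0] = 1.0
                    part /= m[:, :, None]
                    scale += np.log(m)
        partials[node.index] = part
        logscale[node.index] = scale
    root = tree.root.index
    lik = partials[root] @ model.pi
    return lik, logscale[root]


def mixture_loglikelihood(
    tree: Tree, leaf_codons: dict[str, np.ndarray], model: CodonModel
) -> float:
    lik, logscale = pruning_site_likelihoods(tree, leaf_codons, model)
    w = model.mixture.weights[:, None]
    m = logscale.max(axis=0)
    site = (w * lik * np.exp(logscale - m[None, :])).sum(axis=0)
    site = np.maximum(site, 1e-300)
    return float((np.log(site) + m).sum())


def brute_force_loglikelihood(
    tree: Tree, leaf_codons: dict[str, np.ndarray], model: CodonModel
) -> float:
    """Exhaustive summation over all ancestral states (tiny trees only)."""
    internal = [n for n in tree.nodes if not n.is_leaf]
    if NCODON ** len(internal) > 61**3:
        raise ValueError("too many internal nodes for exhaustive summation")
    nsites = len(next(iter(leaf_codons.values())))
    pmats = {
        n.index: model.transition_matrices(n.length)
        for n in tree.nodes
        if n.parent is not None
    }
    nclass = len(model.qs)
    total = np.zeros((nclass, nsites))
    import itertools

    for assign in itertools.product(range(NCODON), repeat=len(internal)):
        states = {n.index: assign[k] for k, n in enumerate(internal)}
        lik = np.ones((nclass, nsites))
        for n in tree.nodes:
            if n.parent is None:
                continue
            ps = states[n.parent.index]
            if n.is_leaf:
                codes = leaf_codons[n.name]
                contrib = np.ones((nclass, nsites))
                known = codes >= 0
                contrib[:, known] = pmats[n.index][:, ps, codes[known]]
            else:
                contrib = np.repeat(
                    pmats[n.index][:, ps, states[n.index]][:, None], nsites, axis=1
                )
            lik *= contrib
        total += lik * model.pi[states[tree.root.index]]
    w = model.mixture.weights[:, None]
    site = (w * total).sum(axis=0)
    return float(np.log(site).sum())
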