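"""Synthetic plastome construction and evolution with ground truth.

``build_ancestor`` assembles a circular quadripartite genome from a gene
plan: LSC, IRb, SSC, IRa in genome order, IRa exactly the reverse
complement of IRb, a ycf1 gene spanning the SSC/IRa junction with its
truncated mirror copy at the IRb/SSC junction, and seven ndh genes in
the SSC.  ``evolve`` runs the genome down a tree under HKY substitutions
with per-class rate multipliers (CDS / intron / IGS), geometric-length
indels confined to non-coding single-copy sequence, SSR slippage at
planted microsatellites, configured ndh deletions/truncations, and
GY94 codon-model evolution overlaid on designated selection genes.
Substitutions sampled inside either IR copy are mirrored into the other,
so the IRs stay identical, as in real plastomes.

Every event is logged against immutable column keys, so the true
multiple alignment and per-segment event counts are exact by
construction.
"""

from __future__ import annotations

import copy as _copy
import json
from bisect import bisect_left
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._codon import SENSE_CODONS, SENSE_INDEX, revcomp
from .codonmodel import CodonModel, OmegaMixture, plastid_like_frequencies
from .genome_io import Feature, PlastomeRecord
from .trees import Tree, TreeNode, parse_newick

_NT = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CLS_IGS, CLS_INTRON, CLS_CDS, CLS_SELECTION = 0, 1, 2, 3
REGIONS = ("LSC", "IRb", "SSC", "IRa")


class ConfigError(ValueError):
    """Invalid evolution configuration."""


# ---------------------------------------------------------------------------
# gene plans


@dataclass(frozen=True)
class PlannedGene:
    name: str
    kind: str              # CDS / tRNA / rRNA / pseudogene
    length: int            # total exonic length (bp)
    strand: str = "+"
    intron: int = 0        # one intron of this length after exon 1, if > 0
    exon1: int = 0         # exon-1 length when intron > 0


def default_length_plan() -> dict[str, int]:
    """Scaled-down plastome proportions: LSC > IR > SSC."""
    return {"LSC": 21500, "IR": 5400, "SSC": 4800}


def default_gene_plan() -> dict[str, list[PlannedGene]]:
    """A plastid-like map: ndh family spread over LSC/IR/SSC (seven in
    the SSC), rpl22 at the LSC/IRb junction, ycf1 at the SSC/IRa one."""
    g = PlannedGene
    lsc = [
        g("psbA", "CDS", 1062, "-"),
        g("matK", "CDS", 1500, "+"),
        g("atpA", "CDS", 1524, "-"),
        g("atpF", "CDS", 555, "-", intron=700, exon1=144),
        g("atpH", "CDS", 246, "-"),
        g("atpI", "CDS", 744, "-"),
        g("rps2", "CDS", 711, "-"),
        g("trnR", "tRNA", 74, "+"),
        g("psbD", "CDS", 1062, "+"),
        g("ndhJ", "CDS", 477, "-"),
        g("ndhK", "CDS", 339, "-"),
        g("ndhC", "CDS", 363, "-"),
        g("atpB", "CDS", 1497, "-"),
        g("rbcL", "CDS", 1434, "+"),
        g("accD", "CDS", 1491, "+"),
        g("clpP", "CDS", 591, "-", intron=600, exon1=246),
        g("psbB", "CDS", 1527, "+"),
        g("psbT", "CDS", 108, "+"),
        g("rps3", "CDS", 657, "+"),
        g("rpl22", "CDS", 417, "+"),
    ]
    irb = [
        g("rps19", "CDS", 279, "-"),
        g("rpl2", "CDS", 825, "-"),
        g("ycf2", "CDS", 1503, "+"),
        g("ndhB", "CDS", 999, "-"),
        g("rrn16", "rRNA", 903, "+"),
    ]
    ssc = [
        g("ndhF", "CDS", 501, "+"),
        g("rpl32", "CDS", 150, "+"),
        g("ccsA", "CDS", 501, "+"),
        g("ndhD", "CDS", 300, "-"),
        g("ndhE", "CDS", 225, "-"),
        g("ndhG", "CDS", 300, "-"),
        g("ndhA", "CDS", 303, "-"),
        g("ndhH", "CDS", 300, "-"),
        g("ndhI", "CDS", 225, "-"),
        g("rps15", "CDS", 273, "+"),
    ]
    return {"LSC": lsc, "IRb": irb, "SSC": ssc}


def _random_background(rng, n: int, at: float) -> list[str]:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return list(_NT[rng.choice(4, size=n, p=np.array([p[0], p[1], p[2], p[3]]))])


def _random_cds(rng, length: int, at: float = 0.64) -> str:
    # AT-biased, slightly A-leaning codon draw (plastid-like: AAA dominates)
    nt = {"A": at * 0.56, "T": at * 0.44, "C": (1 - at) / 2, "G": (1 - at) / 2}
    pi = np.array([nt[c[0]] * nt[c[1]] * nt[c[2]] for c in SENSE_CODONS])
    pi /= pi.sum()
    ncod = length // 3
    body = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), ncod - 2, p=pi)]
    return "ATG" + "".join(body) + "TAA"


@dataclass
class AncestorTruth:
    """Construction byproducts needed by ``evolve`` and by tests."""

    cls: np.ndarray                 # per-base class code
    region: np.ndarray              # per-base region code 0..3
    mirror: dict[int, int]          # IR position pairing (both directions)
    ssr_loci: list[dict]            # planted microsatellites
    gene_spans: dict[str, tuple[int, int]]   # primary span per gene name


def build_ancestor(
    length_plan: dict[str, int] | None = None,
    gene_plan: dict[str, list[PlannedGene]] | None = None,
    seed: int = 0,
    at: float = 0.64,
    ycf1_ir_overlap: int = 402,
    ycf1_ssc_part: int = 900,
    plant_ssrs: bool = True,
) -> tuple[PlastomeRecord, AncestorTruth]:
    """Construct the circular quadripartite ancestor.

    Returns the annotated record plus construction truth (per-base
    class/region codes, the IR mirror map, planted SSR loci).
    """
    plan = dict(length_plan or default_length_plan())
    genes = gene_plan or default_gene_plan()
    L, I, S = plan["LSC"], plan["IR"], plan["SSC"]
    if min(L, I, S) <= 0 or I < 1000:
        raise ConfigError("region lengths must be positive and IR >= 1 kb")
    total = L + 2 * I + S
    rng = np.random.default_rng(seed)
    seq = _random_background(rng, L + I + S, at)
    cls = np.zeros(L + I + S, dtype=np.int8)
    region = np.zeros(L + I + S, dtype=np.int8)
    region[L : L + I] = 1
    region[L + I :] = 2
    features: list[Feature] = []
    gene_spans: dict[str, tuple[int, int]] = {}

    def place_region(genes_here: list[PlannedGene], r0: int, r1: int, tail_gap: int):
        spans = [g.length + g.intron for g in genes_here]
        free = (r1 - r0) - sum(spans) - tail_gap
        if free < len(genes_here):
            raise ConfigError("gene plan overflow in region")
        ngaps = len(genes_here)
        base, extra = divmod(free, ngaps)
        pos = r0
        for gi, g in enumerate(genes_here):
            pos += base + (1 if gi < extra else 0)
            _write_gene(g, pos)
            pos += g.length + g.intron

    def _write_gene(g: PlannedGene, pos: int):
        if g.kind == "CDS":
            cds = _random_cds(rng, g.length)
        else:
            cds = "".join(_random_background(rng, g.length, at))
        if g.intron:
            e1, e2 = g.exon1, g.length - g.exon1
            if g.strand == "+":
                iv1 = (pos, pos + e1)
                iv2 = (pos + e1 + g.intron, pos + e1 + g.intron + e2)
                seq[iv1[0] : iv1[1]] = list(cds[:e1])
                seq[iv2[0] : iv2[1]] = list(cds[e1:])
                parts = (iv1, iv2)
            else:
                iv1 = (pos + e2 + g.intron, pos + e2 + g.intron + e1)
                iv2 = (pos, pos + e2)
                seq[iv1[0] : iv1[1]] = list(revcomp(cds[:e1]))
                seq[iv2[0] : iv2[1]] = list(revcomp(cds[e1:]))
                parts = (iv1, iv2)
            for s0, e0 in parts:
                cls[s0:e0] = CLS_CDS
            lo = min(p[0] for p in parts)
            hi = max(p[1] for p in parts)
            cls[lo:hi][cls[lo:hi] == CLS_IGS] = CLS_INTRON
        else:
            body = cds if g.strand == "+" else revcomp(cds)
            seq[pos : pos + g.length] = list(body)
            cls[pos : pos + g.length] = CLS_CDS
            parts = ((pos, pos + g.length),)
        features.append(Feature(g.name, g.kind, g.strand, parts))
        gene_spans[g.name] = (min(p[0] for p in parts), max(p[1] for p in parts))

    place_region(genes["LSC"], 0, L, tail_gap=8)
    place_region(genes["IRb"], L, L + I, tail_gap=ycf1_ir_overlap + 30)
    # SSC genes, reserving the tail for ycf1's SSC part
    place_region(genes["SSC"], L + I, L + I + S - ycf1_ssc_part, tail_gap=0)

    # ycf1: SSC tail + ycf1_ir_overlap into IRa; the IRa part's reverse
    # complement is written at the IRb end so that IRa == revcomp(IRb).
    ylen = ycf1_ssc_part + ycf1_ir_overlap
    if ylen % 3:
        raise ConfigError("ycf1 length must be a multiple of 3")
    ycds = _random_cds(rng, ylen)
    ystart = L + I + S - ycf1_ssc_part
    seq[ystart : L + I + S] = list(ycds[:ycf1_ssc_part])
    seq[L + I - ycf1_ir_overlap : L + I] = list(revcomp(ycds[ycf1_ssc_part:]))
    cls[ystart : L + I + S] = CLS_CDS
    cls[L + I - ycf1_ir_overlap : L + I] = CLS_CDS
    features.append(Feature("ycf1", "CDS", "+", ((ystart, L + I + S + ycf1_ir_overlap),)))
    features.append(
        Feature("ycf1", "pseudogene", "-", ((L + I - ycf1_ir_overlap, L + I),))
    )
    gene_spans["ycf1"] = (ystart, L + I + S + ycf1_ir_overlap)

    # planted SSRs in LSC intergenic gaps
    ssr_loci: list[dict] = []
    if plant_ssrs:
        ssr_specs = [("A", 12), ("T", 11), ("AT", 6), ("TA", 5), ("AAG", 4), ("ATCC", 3)]
        igs_runs = _runs(cls[:L] == CLS_IGS)
        igs_runs = [r for r in igs_runs if r[1] - r[0] > 80]
        for k, (motif, count) in enumerate(ssr_specs):
            if k >= len(igs_runs):
                break
            s0, e0 = igs_runs[k]
            start = s0 + 20
            span = motif * count
            if start + len(span) + 10 > e0:
                continue
            seq[start : start + len(span)] = list(span)
            # avoid accidental run extension at either end
            seq[start - 1] = "G" if motif[0] != "G" else "C"
            seq[start + len(span)] = "G" if motif[-1] != "G" else "C"
            ssr_loci.append(
                {"motif": motif, "unit": len(motif), "count": count, "start": start}
            )

    # IRa = revcomp(IRb), mirrored features
    ira = list(revcomp("".join(seq[L : L + I])))
    seq = seq + ira
    cls = np.concatenate([cls, np.zeros(I, dtype=np.int8)])
    region = np.concatenate([region, np.full(I, 3, dtype=np.int8)])
    A = L + I + S  # IRa start

    def mirror_pos(p: int) -> int:
        # IRb position p <-> IRa position A + (I - 1 - (p - L))
        return A + I - 1 - (p - L)

    mirror: dict[int, int] = {}
    for p in range(L, L + I):
        q = mirror_pos(p)
        mirror[p] = q
        mirror[q] = p
        cls[q] = cls[p]
    for f in list(features):
        lo, hi = f.start, f.end
        if f.kind == "pseudogene" and f.name == "ycf1":
            continue
        if L <= lo and hi <= L + I:
            nparts = tuple(
                sorted((mirror_pos(e - 1), mirror_pos(s) + 1) for s, e in f.parts)
            )
            strand = "-" if f.strand == "+" else "+"
            if strand == "-":
                nparts = tuple(sorted(nparts, reverse=True))
            features.append(Feature(f.name, f.kind, strand, nparts))

    record = PlastomeRecord(
        id="ancestor",
        sequence="".join(seq),
        circular=True,
        features=features,
        source="synthetic ancestor",
    )
    assert len(record) == total
    truth = AncestorTruth(cls, region, mirror, ssr_loci, gene_spans)
    return record, truth


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# evolution config


def default_study_tree() -> str:
    """Eight-taxon tree, total length ~0.036 substitutions/site."""
    return (
        "((mentosum:0.003,epiphytum:0.003):0.002,((plumosum:0.003,weddellii:0.003)"
        ":0.0015,((exaltatum:0.003,granulosum:0.003):0.0015,(regnellii:0.003,"
        "steyermarkii:0.004):0.002):0.0015):0.0015);"
    )


@dataclass
class EvolutionConfig:
    """Parameters of the synthetic evolution process.

    Rates are per site per unit branch length; ``region_rates`` are
    class multipliers on the branch rate, defaulting to the observed
    CDS : intron : IGS ordering (~2.6 : 3.6 : 5.2 per 100 bp over the
    clade, i.e. 0.72 : 1.0 : 1.45).
    """

    tree: str = field(default_factory=default_study_tree)
    region_rates: dict[str, float] = field(
        default_factory=lambda: {"CDS": 0.72, "intron": 1.0, "IGS": 1.45}
    )
    indel_rate: float = 0.28
    indel_length: float = 0.35        # geometric parameter (mean ~1/p bp)
    ssr_slippage_rate: float = 0.3    # per locus per branch
    ndh_loss_events: list[tuple[str, str, str]] = field(default_factory=list)
    planted_repeats: list[tuple[str, int, int]] = field(default_factory=list)
    selection_genes: list[tuple[str, float, float, float, float]] = field(
        default_factory=list
    )
    kappa: float = 2.0
    at: float = 0.64
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.region_rates.values()):
            raise ConfigError("region rates must be >= 0")
        if self.indel_rate < 0 or self.ssr_slippage_rate < 0:
            raise ConfigError("rates must be >= 0")
        if not (0 < self.indel_length <= 1):
            raise ConfigError("geometric indel parameter must lie in (0, 1]")
        for _, _, action in self.ndh_loss_events:
            if action not in ("delete", "truncate"):
                raise ConfigError(f"unknown ndh event {action!r}")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=2, default=str)


def default_study_config(seed: int = 0) -> EvolutionConfig:
    """The eight-taxon study conditions: independent ndh losses driving
    SSC contraction, two genes under positive selection."""
    return EvolutionConfig(
        ndh_loss_events=[
            ("plumosum", "ndhD", "delete"),
            ("plumosum", "ndhE", "delete"),
            ("plumosum", "ndhG", "delete"),
            ("plumosum", "ndhA", "delete"),
            ("steyermarkii", "ndhG", "delete"),
            ("steyermarkii", "ndhH", "delete"),
            ("steyermarkii", "ndhI", "delete"),
            ("mentosum", "ndhF", "truncate"),
            ("weddellii", "ndhA", "truncate"),
        ],
        selection_genes=[
            ("accD", 0.9, 0.5, 1.5, 3.0),
            ("rps3", 0.95, 0.4, 1.2, 2.5),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth log


@dataclass
class TruthLog:
    """Ground truth of one evolution run, keyed by alignment columns."""

    keys: list[Fraction]                       # all columns, sorted
    rows: dict[str, dict[Fraction, str]]       # node name -> key -> base
    substitutions: list[tuple[str, Fraction]]  # (branch, column)
    indel_events: list[tuple[str, str, tuple[Fraction, ...]]]
    ssr_truth: dict[str, dict[int, int]]       # leaf -> locus index -> count
    planted_ssrs: list[dict]
    planted_repeats: list[dict]
    selection_truth: dict[str, dict]           # gene -> {classes, omegas, positive}
    leaf_names: list[str]

    def column_index(self) -> dict[Fraction, int]:
        return {k: i for i, k in enumerate(self.keys)}

    def alignment(self, include_ancestor: bool = True) -> dict[str, str]:
        idx = self.column_index()
        out = {}
        for name, row in self.rows.items():
            if not include_ancestor and name == "ancestor":
                continue
            arr = ["-"] * len(self.keys)
            for k, ch in row.items():
                arr[idx[k]] = ch
            out[name] = "".join(arr)
        return out

    def substitution_columns(self) -> list[int]:
        idx = self.column_index()
        return [idx[k] for _, k in self.substitutions]

    def indel_event_count_in(self, col_start: int, col_end: int) -> int:
        """Distinct indel events whose span intersects [col_start, col_end)."""
        idx = self.column_index()
        seen = set()
        for _, kind, keys in self.indel_events:
            cols = sorted(idx[k] for k in keys)
            if cols and cols[0] < col_end and cols[-1] >= col_start:
                seen.add((kind, cols[0], cols[-1]))
        return len(seen)

    def substitution_count_in(self, col_start: int, col_end: int) -> int:
        idx = self.column_index()
        return sum(1 for _, k in self.substitutions if col_start <= idx[k] < col_end)


# ---------------------------------------------------------------------------
# the evolver


class _LineageState:
    """Mutable per-node genome state during evolution."""

    __slots__ = ("chars", "keys", "cls", "features", "ssr", "gene_cols")

    def __init__(self, chars, keys, cls, features, ssr, gene_cols):
        self.chars = chars          # list[str]
        self.keys = keys            # list[Fraction], ascending
        self.cls = cls              # list[int] class codes
        self.features = features    # list of [name, kind, strand, parts(list of (k0,k1))]
        self.ssr = ssr              # list of dicts (count, key range) per locus
        self.gene_cols = gene_cols  # gene -> list of keys (selection genes)

    def copy(self) -> "_LineageState":
        return _LineageState(
            list(self.chars),
            list(self.keys),
            list(self.cls),
            _copy.deepcopy(self.features),
            _copy.deepcopy(self.ssr),
            self.gene_cols,
        )


def evolve(
    ancestor: PlastomeRecord,
    config: EvolutionConfig,
    ancestor_truth: AncestorTruth | None = None,
) -> tuple[list[PlastomeRecord], TruthLog]:
    """Evolve the ancestor along the configured tree.

    Returns one annotated record per leaf plus the complete TruthLog.
    """
    config.validate()
    if ancestor_truth is None:
        raise ConfigError("evolve requires the AncestorTruth from build_ancestor")
    tree = parse_newick(config.tree)
    node_names = {n.name for n in tree.nodes}
    for branch, gene, _ in config.ndh_loss_events:
        if branch not in node_names:
            raise ConfigError(f"ndh event on unknown branch {branch!r}")
        if gene not in ancestor_truth.gene_spans:
            raise ConfigError(f"ndh event on unknown gene {gene!r}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = len(ancestor)
    seq = list(ancestor.sequence)
    cls = list(ancestor_truth.cls)
    keys = [Fraction(i) for i in range(n)]

    # planted long repeats (modify the ancestor before evolution)
    planted_repeats = _plant_repeats(seq, cls, ancestor_truth, config, rng)

    # mark selection-gene columns
    gene_cols: dict[str, list[Fraction]] = {}
    sel_feats: dict[str, Feature] = {}
    for gene, *_params in config.selection_genes:
        feats = [
            f for f in ancestor.features if f.name == gene and f.kind == "CDS"
        ]
        if not feats or len(feats[0].parts) != 1:
            raise ConfigError(f"selection gene {gene!r} must be a single-part CDS")
        f = feats[0]
        s0, e0 = f.parts[0]
        if any(p in ancestor_truth.mirror for p in (s0, e0 - 1)):
            raise ConfigError(f"selection gene {gene!r} may not touch the IRs")
        gene_cols[gene] = [Fraction(p) for p in range(s0, e0)]
        sel_feats[gene] = f
        for p in range(s0, e0):
            cls[p] = CLS_SELECTION

    # ndh genes overlapping the IRs cannot be deleted (mirroring)
    for branch, gene, action in config.ndh_loss_events:
        s0, e0 = ancestor_truth.gene_spans[gene]
        if action == "delete" and any(
            p in ancestor_truth.mirror for p in (s0, e0 - 1)
        ):
            raise ConfigError(f"cannot delete IR gene {gene!r}")

    # pre-simulate selection genes on every node
    sel_states, selection_truth = _simulate_selection_genes(
        tree, ancestor, sel_feats, config, rng
    )

    ssr_state = [
        {
            "motif": loc["motif"],
            "unit": loc["unit"],
            "count": loc["count"],
            "k0": Fraction(loc["start"]),
            "keys": [Fraction(p) for p in range(loc["start"], loc["start"] + loc["unit"] * loc["count"])],
        }
        for loc in ancestor_truth.ssr_loci
    ]
    features0 = [
        [f.name, f.kind, f.strand, [(Fraction(s), Fraction(e - 1)) for s, e in f.parts],
         f.codon_start]
        for f in ancestor.features
    ]
    root_state = _LineageState(seq, keys, cls, features0, ssr_state, gene_cols)
    mirror_key = {Fraction(a): Fraction(b) for a, b in ancestor_truth.mirror.items()}

    all_keys: set[Fraction] = set(keys)
    rows: dict[str, dict[Fraction, str]] = {}
    substitutions: list[tuple[str, Fraction]] = []
    indel_events: list[tuple[str, str, tuple[Fraction, ...]]] = []
    ssr_truth: dict[str, dict[int, int]] = {}
    leaf_states: dict[str, _LineageState] = {}

    mult = {
        CLS_IGS: config.region_rates["IGS"],
        CLS_INTRON: config.region_rates["intron"],
        CLS_CDS: config.region_rates["CDS"],
    }
    pi_nt = np.array(
        [config.at / 2, (1 - config.at) / 2, (1 - config.at) / 2, config.at / 2]
    )
    jump = _hky_jump_matrix(pi_nt, config.kappa)
    ndh_by_branch: dict[str, list[tuple[str, str]]] = {}
    for branch, gene, action in config.ndh_loss_events:
        ndh_by_branch.setdefault(branch, []).append((gene, action))

    def process(state: _LineageState, node: TreeNode) -> None:
        if node.is_leaf:
            leaf_states[node.name] = state
            return
        for child in node.children:
            st = state.copy()
            t = child.length
            _apply_ndh_events(
                st, ndh_by_branch.get(child.name, ()), child.name, indel_events, rng
            )
            _apply_indels(
                st, t, config, child.name, indel_events, all_keys, mirror_key, rng
            )
            _apply_slippage(st, config, child.name, indel_events, all_keys, rng)
            _apply_substitutions(
                st, t, mult, jump, mirror_key, child.name, substitutions, rng
            )
            _overlay_selection(st, sel_states, child.name)
            process(st, child)

    # record ancestor row, then evolve
    process(root_state, tree.root)
    rows["ancestor"] = dict(zip(root_state.keys, root_state.chars))
    for name, st in leaf_states.items():
        rows[name] = dict(zip(st.keys, st.chars))
        ssr_truth[name] = {i: loc["count"] for i, loc in enumerate(st.ssr)}

    records = [
        _materialize(name, leaf_states[name]) for name in sorted(leaf_states)
    ]
    truth = TruthLog(
        keys=sorted(all_keys),
        rows=rows,
        substitutions=substitutions,
        indel_events=indel_events,
        ssr_truth=ssr_truth,
        planted_ssrs=ancestor_truth.ssr_loci,
        planted_repeats=planted_repeats,
        selection_truth=selection_truth,
        leaf_names=sorted(leaf_states),
    )
    return records, truth


def _hky_jump_matrix(pi: np.ndarray, kappa: float) -> np.ndarray:
    """Conditional jump distribution given a substitution occurs."""
    nt = "ACGT"
    J = np.zeros((4, 4))
    for i, a in enumerate(nt):
        for j, b in enumerate(nt):
            if i == j:
                continue
            ts = {a, b} in ({"A", "G"}, {"C", "T"})
            J[i, j] = pi[j] * (kappa if ts else 1.0)
        J[i] /= J[i].sum()
    return J


def _plant_repeats(seq, cls, truth: AncestorTruth, config, rng) -> list[dict]:
    out = []
    lsc_igs = _runs(
        (truth.cls == CLS_IGS) & (truth.region == 0)
    )
    lsc_igs = [r for r in lsc_igs if r[1] - r[0] > 60]
    ri = 0
    for klass, length, mismatches in config.planted_repeats:
        src = tgt = None
        while ri + 1 < len(lsc_igs):
            a, b = lsc_igs[ri], lsc_igs[ri + 1]
            ri += 2
            if b[1] - b[0] >= length + 20 and a[1] - a[0] >= length + 20:
                src, tgt = a, b
                break
        if src is None:
            break
        s0 = src[0] + 5
        t0 = tgt[0] + 5
        piece = "".join(seq[s0 : s0 + length])
        if klass == "reverse":
            piece = piece[::-1]
        elif klass == "palindromic":
            piece = revcomp(piece)
        piece = list(piece)
        mm_pos = rng.choice(length, size=mismatches, replace=False) if mismatches else []
        for p in mm_pos:
            cur = piece[p]
            piece[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
        seq[t0 : t0 + length] = piece
        out.append(
            {
                "class": klass,
                "length": length,
                "mismatches": mismatches,
                "pos1": (s0, s0 + length),
                "pos2": (t0, t0 + length),
            }
        )
    return out


def _key_index(st: _LineageState) -> dict[Fraction, int]:
    return {k: i for i, k in enumerate(st.keys)}


def _apply_ndh_events(st, events, branch, indel_events, rng) -> None:
    for gene, action in events:
        feat = next(
            (f for f in st.features if f[0] == gene and f[1] == "CDS"), None
        )
        if feat is None:
            raise ConfigError(f"{branch}: gene {gene!r} not present for ndh event")
        if action == "delete":
            k0 = min(k for k, _ in feat[3])
            k1 = max(k for _, k in feat[3])
            i0 = bisect_left(st.keys, k0)
            i1 = bisect_left(st.keys, k1) + 1
            removed = tuple(st.keys[i0:i1])
            del st.keys[i0:i1]
            del st.chars[i0:i1]
            del st.cls[i0:i1]
            st.features.remove(feat)
            indel_events.append((branch, "del", removed))
        else:  # truncate: premature stop ~1/3 into the reading frame
            k0, _k1 = feat[3][0]
            idx = _key_index(st)
            parts_keys: list[Fraction] = []
            for a, b in sorted(feat[3]):
                ia, ib = idx[a], idx[b]
                parts_keys.extend(st.keys[ia : ib + 1])
            ncod = len(parts_keys) // 3
            stop_at = max(1, ncod // 3)
            codon_keys = parts_keys[3 * stop_at : 3 * stop_at + 3]
            # genome-order write: TAA on +, revcomp(TAA) on - (frame aligns
            # with genome-order triplets because the length is a 3-multiple)
            written = "TAA" if feat[2] == "+" else revcomp("TAA")
            for k, ch in zip(codon_keys, written):
                st.chars[idx[k]] = ch
            feat[1] = "pseudogene"


def _apply_indels(st, t, config, branch, indel_events, all_keys, mirror_key, rng) -> None:
    ssr_keys = {k for loc in st.ssr for k in loc["keys"]}

    def collect_eligible():
        # non-coding, single-copy, non-SSR only: indels inside the IRs would
        # break substitution mirroring; SSR length changes belong to the
        # slippage process
        return [
            i
            for i, c in enumerate(st.cls)
            if c in (CLS_IGS, CLS_INTRON)
            and st.keys[i] not in mirror_key
            and st.keys[i] not in ssr_keys
        ]

    eligible = collect_eligible()
    n_ev = rng.poisson(config.indel_rate * t * len(eligible))
    for _ in range(n_ev):
        if not eligible:
            break
        anchor = int(rng.choice(eligible))
        length = int(rng.geometric(config.indel_length))
        is_del = rng.random() < 0.5
        c = st.cls[anchor]
        # bound the event inside the contiguous same-class run
        hi = anchor
        while (
            hi < len(st.cls) - 1
            and st.cls[hi + 1] == c
            and st.keys[hi + 1] not in mirror_key
            and st.keys[hi + 1] not in ssr_keys
        ):
            hi += 1
        if is_del:
            end_excl = min(anchor + length, hi + 1)
            if end_excl <= anchor:
                continue
            removed = tuple(st.keys[anchor:end_excl])
            del st.keys[anchor:end_excl]
            del st.chars[anchor:end_excl]
            del st.cls[anchor:end_excl]
            indel_events.append((branch, "del", removed))
        else:
            left = st.keys[anchor]
            right = st.keys[anchor + 1] if anchor + 1 < len(st.keys) else left + 1
            newkeys = [
                left + (right - left) * Fraction(j + 1, length + 1)
                for j in range(length)
            ]
            bases = list(
                _NT[rng.integers(0, 4, size=length)]
            )
            st.keys[anchor + 1 : anchor + 1] = newkeys
            st.chars[anchor + 1 : anchor + 1] = bases
            st.cls[anchor + 1 : anchor + 1] = [c] * length
            all_keys.update(newkeys)
            indel_events.append((branch, "ins", tuple(newkeys)))
        eligible = collect_eligible()


def _apply_slippage(st, config, branch, indel_events, all_keys, rng) -> None:
    for loc in st.ssr:
        if rng.random() >= config.ssr_slippage_rate:
            continue
        unit = loc["unit"]
        grow = rng.random() < 0.5 or loc["count"] <= 3
        idx = _key_index(st)
        kidx = [idx[k] for k in loc["keys"]]
        if grow:
            last = kidx[-1]
            left = st.keys[last]
            right = st.keys[last + 1] if last + 1 < len(st.keys) else left + 1
            newkeys = [
                left + (right - left) * Fraction(j + 1, unit + 1) for j in range(unit)
            ]
            motif_now = "".join(st.chars[i] for i in kidx[-unit:])
            st.keys[last + 1 : last + 1] = newkeys
            st.chars[last + 1 : last + 1] = list(motif_now)
            st.cls[last + 1 : last + 1] = [st.cls[last]] * unit
            all_keys.update(newkeys)
            loc["keys"] = loc["keys"] + newkeys
            loc["count"] += 1
            indel_events.append((branch, "ins", tuple(newkeys)))
        else:
            drop = kidx[-unit:]
            removed = tuple(st.keys[i] for i in drop)
            for i in sorted(drop, reverse=True):
                del st.keys[i]
                del st.chars[i]
                del st.cls[i]
            loc["keys"] = loc["keys"][:-unit]
            loc["count"] -= 1
            indel_events.append((branch, "del", removed))


def _apply_substitutions(
    st, t, mult, jump, mirror_key, branch, substitutions, rng
) -> None:
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    idx = _key_index(st)
    ssr_keys = {k for loc in st.ssr for k in loc["keys"]}
    by_class: dict[int, list[int]] = {CLS_IGS: [], CLS_INTRON: [], CLS_CDS: []}
    for i, c in enumerate(st.cls):
        if c not in by_class:
            continue
        k = st.keys[i]
        if k in ssr_keys:
            continue  # microsatellite length/composition evolves by slippage
        partner = mirror_key.get(k)
        if partner is not None and partner < k:
            continue  # sample each IR site once (in IRb); the hit is mirrored
        by_class[c].append(i)
    for c, positions in by_class.items():
        if not positions:
            continue
        n_ev = rng.poisson(mult[c] * t * len(positions))
        for _ in range(n_ev):
            i = positions[int(rng.integers(0, len(positions)))]
            cur = st.chars[i]
            if cur not in nt_index:
                continue
            new = _NT[rng.choice(4, p=jump[nt_index[cur]])]
            st.chars[i] = str(new)
            substitutions.append((branch, st.keys[i]))
            partner = mirror_key.get(st.keys[i])
            if partner is not None and partner in idx:
                st.chars[idx[partner]] = _COMP[str(new)]


def _overlay_selection(st, sel_states, branch) -> None:
    idx = None
    for gene, per_node in sel_states.items():
        if branch not in per_node:
            continue
        if idx is None:
            idx = _key_index(st)
        seq = per_node[branch]
        for k, ch in zip(st.gene_cols[gene], seq):
            st.chars[idx[k]] = ch


def _simulate_selection_genes(tree, ancestor, sel_feats, config, rng):
    """GY94 evolution of the selection genes on every tree node."""
    sel_states: dict[str, dict[str, str]] = {}
    selection_truth: dict[str, dict] = {}
    if not sel_feats:
        return sel_states, selection_truth
    pi = plastid_like_frequencies(config.at)
    for gene, p0, p, q, omega_s in config.selection_genes:
        f = sel_feats[gene]
        s0, e0 = f.parts[0]
        gene_nt = ancestor.sequence[s0:e0]
        if f.strand == "-":
            gene_nt = revcomp(gene_nt)
        ncod = len(gene_nt) // 3
        mixture = OmegaMixture.m8(p0, p, q, omega_s, ncat=10)
        model = CodonModel(config.kappa, mixture, pi)
        classes = rng.choice(
            len(mixture.omegas), size=ncod, p=mixture.weights
        )
        root_codons = np.array(
            [
                SENSE_INDEX.get(gene_nt[3 * i : 3 * i + 3], 0)
                for i in range(ncod)
            ]
        )
        states = _evolve_codons(tree, model, classes, root_codons, rng)
        per_node: dict[str, str] = {}
        for name, codons in states.items():
            cds = "".join(SENSE_CODONS[c] for c in codons)
            per_node[name] = cds if f.strand == "+" else revcomp(cds)
        sel_states[gene] = per_node
        selection_truth[gene] = {
            "classes": classes.tolist(),
            "omegas": mixture.omegas.tolist(),
            "positive": [
                i
                for i, c in enumerate(classes)
                if c == mixture.positive_class and omega_s > 1.0
            ],
            "params": {"p0": p0, "p": p, "q": q, "omega_s": omega_s},
        }
    return sel_states, selection_truth


def _evolve_codons(tree, model, classes, root_codons, rng) -> dict[str, np.ndarray]:
    """Sample codon states for every node given per-site class labels."""
    states: dict[str, np.ndarray] = {tree.root.name: root_codons}
    order = [n for n in reversed(tree.nodes)]  # root first (preorder-ish)
    for node in order:
        if node.parent is None:
            continue
        parent_states = states[node.parent.name]
        P = model.transition_matrices(node.length)  # (nclass, 61, 61)
        child = np.empty_like(parent_states)
        for s, (cl, ps) in enumerate(zip(classes, parent_states)):
            child[s] = rng.choice(len(model.pi), p=P[cl, ps])
        states[node.name] = child
    return states


def simulate_codon_gene(
    tree: str | Tree,
    m8_params: tuple[float, float, float, float, float],
    n_codons: int,
    seed: int = 0,
    pi: np.ndarray | None = None,
    ncat: int = 10,
) -> tuple[dict[str, str], np.ndarray]:
    """Simulate one codon alignment under the M8 mixture.

    ``m8_params`` = (p0, p, q, omega_s, kappa).  Returns the leaf codon
    alignment (name -> nucleotide string) and the true per-site class
    labels (the last class is the omega_s class).
    """
    p0, p, q, omega_s, kappa = m8_params
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if omega_s < 1.0:
        raise ValueError("omega_s must be >= 1")
    t = parse_newick(tree) if isinstance(tree, str) else tree
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = plastid_like_frequencies()
    mixture = OmegaMixture.m8(p0, p, q, omega_s, ncat=ncat)
    model = CodonModel(kappa, mixture, pi)
    classes = rng.choice(len(mixture.omegas), size=n_codons, p=mixture.weights)
    root = rng.choice(len(pi), size=n_codons, p=pi)
    states = _evolve_codons(t, model, classes, root, rng)
    leaves = {
        name: "".join(SENSE_CODONS[c] for c in states[name])
        for name in t.leaf_names
    }
    return leaves, classes


def simulate_study(
    config: EvolutionConfig | None = None,
    length_plan: dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[PlastomeRecord, list[PlastomeRecord], TruthLog]:
    """Build the default ancestor and evolve it under ``config``.

    Convenience wrapper returning (ancestor, leaf records, truth log).
    """
    if config is None:
        config = default_study_config(seed if seed is not None else 0)
    elif seed is not None:
        config.seed = seed
    ancestor, atruth = build_ancestor(length_plan=length_plan, seed=config.seed)
    records, truth = evolve(ancestor, config, atruth)
    return ancestor, records, truth


def _materialize(name: str, st: _LineageState) -> PlastomeRecord:
    idx = _key_index(st)
    feats = []
    for fname, kind, strand, parts, codon_start in st.features:
        iv = []
        for k0, k1 in parts:
            if k0 not in idx or k1 not in idx:
                continue
            iv.append((idx[k0], idx[k1] + 1))
        if not iv:
            continue
        iv.sort(reverse=(strand == "-"))
        feats.append(Feature(fname, kind, strand, tuple(iv), codon_start))
    return PlastomeRecord(
        id=name,
        sequence="".join(st.chars),
        circular=True,
        features=feats,
        source="synthetic leaf",
    )
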