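"""Configuration-driven orchestration of the analysis stages.

Stages run in dependency order: io -> structure -> codon ->
repeats/ssrs -> variability -> selection.  Every run writes a config
echo with resolved defaults; identical config + seed reproduces
identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_usage as cu
from . import repeats as rp
from . import structure as st
from . import variability as vb
from .genome_io import PlastomeRecord, read_annotated_genome, region_class_map, gc_content, write_genome
from .selection import scan_gene
from .synthetic import EvolutionConfig, default_study_config, simulate_study

log = logging.getLogger("plastocomp")

ALL_STAGES = ("structure", "codon", "repeats", "ssrs", "variability", "selection")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    ``simulate`` holds EvolutionConfig overrides (or True for the
    default study conditions); alternatively ``genomes`` lists input
    GenBank paths.  ``alignment`` is an aligned-FASTA path or
    "from-truth" (simulated runs only).
    """

    out_dir: str = "plastocomp_out"
    seed: int = 0
    simulate: dict | bool | None = None
    genomes: list[str] = field(default_factory=list)
    alignment: str = "from-truth"
    reference: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    ir_min_len: int | None = None     # None -> min(10000, genome/7)
    repeat_min_len: int = 30
    repeat_max_mismatch: int = 3
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(rp.DEFAULT_SSR_THRESHOLDS)
    )
    segment_min_len: int = 150
    top_k: int = 10
    polymorphic_min_species: int = 4
    selection_genes: list[str] = field(default_factory=list)
    n_beta_categories: int = 10
    log_level: str = "INFO"

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**d)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise PipelineConfigError(f"unknown stages: {sorted(bad)}")
        if isinstance(cfg.ssr_thresholds, dict):
            cfg.ssr_thresholds = {int(k): int(v) for k, v in cfg.ssr_thresholds.items()}
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the JSON summary dict."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = asdict(config)
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2, default=str, sort_keys=True))

    truth = None
    if config.simulate is not None and config.simulate is not False:
        sim_cfg = default_study_config(config.seed)
        if isinstance(config.simulate, dict):
            for k, v in config.simulate.items():
                if not hasattr(sim_cfg, k):
                    raise PipelineConfigError(f"unknown simulate key {k!r}")
                setattr(sim_cfg, k, v)
        sim_cfg.seed = config.seed
        log.info("simulating study clade (seed=%d)", config.seed)
        ancestor, records, truth = simulate_study(sim_cfg)
        gdir = out / "genomes"
        gdir.mkdir(exist_ok=True)
        for rec in records:
            write_genome(rec, gdir / f"{rec.id}.gb")
        aln = truth.alignment()
        with open(out / "true_alignment.fasta", "w") as fh:
            for name, row in aln.items():
                fh.write(f">{name}\n{row}\n")
    elif config.genomes:
        records = [read_annotated_genome(p) for p in config.genomes]
    else:
        raise PipelineConfigError("either 'simulate' or 'genomes' is required")
    if not records:
        raise PipelineConfigError("no input genomes")

    summary: dict = {"n_genomes": len(records), "genomes": {}}
    maps = {rec.id: region_class_map(rec) for rec in records}
    partitions = {}

    if "structure" in config.stages:
        rows = []
        for rec in records:
            min_len = config.ir_min_len or min(10_000, len(rec) // 7)
            part = st.detect_inverted_repeat(rec, min_len=min_len)
            partitions[rec.id] = part
            lengths = part.lengths
            rows.append(
                {
                    "id": rec.id,
                    "total_bp": len(rec),
                    "LSC_bp": lengths["LSC"],
                    "SSC_bp": lengths["SSC"],
                    "IR_bp": part.ir_length(),
                    "gc": round(gc_content(rec), 4),
                    "ir_ssc_type": st.classify_ir_ssc_type(rec, part).type_number,
                }
            )
            summary["genomes"][rec.id] = {
                "total": len(rec),
                "LSC": lengths["LSC"],
                "SSC": lengths["SSC"],
                "IR": part.ir_length(),
                "tiles": lengths["LSC"] + lengths["SSC"] + lengths["IRa"] + lengths["IRb"]
                == len(rec),
            }
        pd.DataFrame(rows).to_csv(out / "partition_table.tsv", sep="\t", index=False)
        jrows = []
        for rec in records:
            for jc in st.junction_report(rec, partitions[rec.id]):
                jrows.append(
                    {"id": rec.id, "junction": jc.junction, "feature": jc.feature,
                     "overlap_bp": jc.overlap}
                )
        pd.DataFrame(jrows).to_csv(out / "junction_table.tsv", sep="\t", index=False)
        ref_lengths = _ndh_reference_lengths(records)
        audit = st.ndh_audit(records, ref_lengths)
        pd.DataFrame(audit).T.to_csv(out / "ndh_status.tsv", sep="\t")
        if len(records) >= 3 and partitions:
            try:
                r, p = st.ndh_ssc_correlation(records, partitions)
                summary["ndh_ssc_pearson_r"] = round(r, 4)
                summary["ndh_ssc_p"] = p
            except ValueError:
                pass
            ssc = [partitions[r_.id].region_length("SSC") for r_ in records]
            tot = [len(r_) for r_ in records]
            try:
                reg = st.length_regression(ssc, tot)
                summary["ssc_total_r2"] = round(reg.r_squared, 4)
                summary["ssc_total_F"] = round(reg.f_statistic, 2)
            except ValueError:
                pass

    if "codon" in config.stages:
        tables = {rec.id: cu.genome_codon_usage(rec) for rec in records}
        for gid, tab in tables.items():
            tab.to_frame().to_csv(out / f"codon_usage_{gid}.tsv", sep="\t", index=False)
        cu.usage_matrix(tables).to_csv(out / "rscu_matrix.tsv", sep="\t")
        audit = cu.start_codon_audit(records)
        pd.DataFrame(audit, columns=["gene", "genome", "start_codon"]).to_csv(
            out / "start_codon_audit.tsv", sep="\t", index=False
        )
        summary["codon_totals"] = {g: t.total_sense for g, t in tables.items()}

    if "repeats" in config.stages and partitions:
        rrows = []
        for rec in records:
            hits = rp.find_long_repeats(
                rec.sequence, config.repeat_min_len, config.repeat_max_mismatch
            )
            annotated, counts = rp.classify_hits(hits, partitions[rec.id], maps[rec.id])
            for h in annotated:
                rrows.append(
                    {"id": rec.id, "class": h.klass, "length": h.length,
                     "mismatches": h.mismatches, "start1": h.pos1[0], "end1": h.pos1[1],
                     "start2": h.pos2[0], "end2": h.pos2[1], "region": h.region,
                     "region_class": h.region_class}
                )
        pd.DataFrame(rrows).to_csv(out / "repeat_table.tsv", sep="\t", index=False)
        summary["n_repeats"] = len(rrows)

    if "ssrs" in config.stages and partitions:
        srows = []
        per_species = {}
        for rec in records:
            loci = rp.scan_ssrs(rec.sequence, config.ssr_thresholds)
            annotated, counts = rp.classify_hits(loci, partitions[rec.id], maps[rec.id])
            per_species[rec.id] = (rec.sequence, loci)
            for l in annotated:
                srows.append(
                    {"id": rec.id, "motif": l.motif, "unit": l.unit, "count": l.count,
                     "start": l.start, "end": l.end, "region": l.region,
                     "region_class": l.region_class}
                )
        pd.DataFrame(srows).to_csv(out / "ssr_table.tsv", sep="\t", index=False)
        groups = rp.polymorphic_ssrs(
            per_species, min_species=config.polymorphic_min_species
        )
        grows = [
            {"motif": g.motif, "n_species": g.n_species,
             "counts": ";".join(f"{k}={v}" for k, v in sorted(g.counts.items()))}
            for g in groups
        ]
        pd.DataFrame(grows).to_csv(out / "polymorphic_ssrs.tsv", sep="\t", index=False)
        summary["n_ssrs"] = len(srows)
        summary["n_polymorphic_ssr_groups"] = len(groups)

    if "variability" in config.stages:
        aln = None
        if config.alignment == "from-truth":
            if truth is None:
                raise PipelineConfigError(
                    "'from-truth' alignment requires the simulate stage"
                )
            aln = truth.alignment(include_ancestor=False)
        else:
            aln = _read_fasta(config.alignment)
        ref_id = config.reference or records[0].id
        segments = vb.segment_alignment(
            aln, maps[ref_id], ref_id, min_len=config.segment_min_len
        )
        vb.segments_frame(segments).to_csv(out / "segments.tsv", sep="\t", index=False)
        rt = vb.rate_table(segments)
        rt.rounded().to_csv(out / "rate_table.tsv", sep="\t")
        top = vb.rank_segments(segments, config.top_k)
        vb.segments_frame(top).to_csv(out / "top_markers.tsv", sep="\t", index=False)
        summary["n_segments"] = len(segments)
        summary["top_markers"] = [s.name for s in top]
        try:
            r, p = vb.sv_at_correlation(segments)
            summary["sv_at_r"] = round(r, 4)
        except ValueError:
            pass

    if "selection" in config.stages:
        genes = list(config.selection_genes)
        if not genes and truth is not None:
            genes = list(truth.selection_truth)
        sel_rows = []
        for gene in genes:
            gene_aln = _stack_gene_alignment(records, gene)
            if gene_aln is None:
                log.warning("gene %s not alignable across genomes; skipped", gene)
                continue
            res = scan_gene(gene, gene_aln, n_beta_categories=config.n_beta_categories)
            sel_rows.append(
                {"gene": gene, "lnl_m0": res.m0.lnl, "lnl_m8a": res.m8a.lnl,
                 "lnl_m8": res.m8.lnl, "kappa": res.m8.kappa, "p0": res.m8.p0,
                 "p": res.m8.p, "q": res.m8.q, "omega_s": res.m8.omega_s,
                 "lrt_stat": res.lrt_stat, "lrt_p": res.lrt_p,
                 "n_positive_sites": res.n_positive,
                 "mean_branch_length": res.mean_branch_length}
            )
        pd.DataFrame(sel_rows).to_csv(out / "selection_table.tsv", sep="\t", index=False)
        summary["selection"] = {
            r["gene"]: {"n_positive": r["n_positive_sites"], "lrt_p": r["lrt_p"]}
            for r in sel_rows
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _ndh_reference_lengths(records: list[PlastomeRecord]) -> dict[str, int]:
    ref: dict[str, int] = {}
    for rec in records:
        for gene in st.NDH_GENES:
            for f in rec.features_named(gene):
                if f.kind == "CDS":
                    ref[gene] = max(ref.get(gene, 0), f.length)
    return ref


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def _stack_gene_alignment(records, gene) -> dict[str, str] | None:
    from .genome_io import extract_feature_sequence

    seqs = {}
    for rec in records:
        feats = [f for f in rec.features_named(gene) if f.kind == "CDS"]
        if not feats:
            return None
        seqs[rec.id] = extract_feature_sequence(rec, feats[0])
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        return None
    return seqs
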