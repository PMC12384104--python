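"""End-to-end orchestration: differential expression -> differential
methylation -> network assembly -> FFL discovery -> enrichment.

The pipeline runs either from a :class:`PipelineConfig` (file paths +
parameters, resolved from YAML by the CLI) or directly from an in-memory
:class:`~fflscope.synthetic_data.StudyInputs` bundle. Every run emits the
intermediate TSVs, a deterministic ``report.json`` with all per-stage
counts, and a ``manifest.json`` with stage timings, the resolved config
and input checksums. Rerunning with the same inputs and seed reproduces
``report.json`` byte for byte.

Sample-intersection policy: methylation/RNA stages use the samples shared
by the beta and RNA matrices; miRNA correlations use the intersection with
the miRNA assay (the motivating cohorts differ: 134/84 vs 129/56).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diff_expression as de_mod
from . import diff_methylation as dm_mod
from . import enrichment as enr_mod
from . import ffl_discovery as ffl_mod
from . import network_assembly as net_mod
from .io_formats import (
    EDGE_CLASSES,
    InteractionTable,
    ValidationError,
    read_category_map,
    read_gene_annotation,
    read_gmt,
    read_interactions,
    read_matrix,
    read_motif_occurrences,
    read_motif_tf_map,
    read_probe_annotation,
    read_sample_sheet,
)
from .synthetic_data import StudyInputs

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineParams:
    """All thresholds of the workflow; defaults are the published settings
    (0.3 / 0.01 / 0.05 / 1.1 / 10 for the methylation arm, +-0.58 at
    p < 0.05 for expression, p < 0.05 for correlation signing)."""

    sig_diff: float = 0.3
    diffmeth_p: float = 0.01
    pair_raw_p: float = 0.05
    motif_lower_or: float = 1.1
    motif_min_incidence: int = 10
    lfc_cut: float = 0.58
    de_p: float = 0.05
    mrtf_p: float = 0.05
    r_p_cut: float = 0.05
    n_perm: int = 10000
    n_random_networks: int = 1000
    n_swaps_per_edge: int = 10
    k_candidate_genes: int = 10
    mu_frac: float = 0.2
    mu_min_per_side: int = 5
    enrichment_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diffmeth_p", "pair_raw_p", "de_p", "mrtf_p", "r_p_cut", "enrichment_fdr"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.sig_diff < 0 or self.lfc_cut < 0:
            raise ValidationError("sig_diff and lfc_cut must be >= 0")
        if self.motif_lower_or < 0 or self.motif_min_incidence < 0:
            raise ValidationError("motif thresholds must be >= 0")


@dataclasses.dataclass
class PipelineConfig:
    """File-path configuration, typically loaded from YAML."""

    beta: str
    gene_counts: str
    mirna_counts: str
    samples: str
    probes: str
    genes: str
    motif_occurrences: str
    motif_tf_map: str
    interactions_tf_gene: str
    interactions_tf_mir: str
    interactions_mir_gene: str
    interactions_mir_tf: str
    gene_sets: str | None = None
    category_map: str | None = None
    de_table: str | None = None  # optional externally produced DE table (genes/TFs)
    params: PipelineParams = dataclasses.field(default_factory=PipelineParams)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = PipelineParams(**raw.pop("params", {}))
    return PipelineConfig(params=params, **raw)


def load_inputs(config: PipelineConfig) -> StudyInputs:
    return StudyInputs(
        beta=read_matrix(config.beta, "beta"),
        gene_counts=read_matrix(config.gene_counts, "counts"),
        mirna_counts=read_matrix(config.mirna_counts, "counts"),
        sheet=read_sample_sheet(config.samples),
        probe_ann=read_probe_annotation(config.probes),
        gene_ann=read_gene_annotation(config.genes),
        motif_occurrences=read_motif_occurrences(config.motif_occurrences),
        motif_tf_map=read_motif_tf_map(config.motif_tf_map),
        interactions={
            "TF-GENE": read_interactions(config.interactions_tf_gene, "TF-GENE"),
            "TF-MIR": read_interactions(config.interactions_tf_mir, "TF-MIR"),
            "MIR-GENE": read_interactions(config.interactions_mir_gene, "MIR-GENE"),
            "MIR-TF": read_interactions(config.interactions_mir_tf, "MIR-TF"),
        },
        gene_sets=read_gmt(config.gene_sets) if config.gene_sets else None,
        category_map=read_category_map(config.category_map) if config.category_map else {},
    )


def run_study(
    inputs: StudyInputs,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
    external_de: pd.DataFrame | None = None,
) -> dict:
    """Run the full workflow on an in-memory bundle; returns the report.

    When ``outdir`` is given, all intermediate TSVs plus ``report.json``
    and ``manifest.json`` are written there.
    """
    params = params or PipelineParams()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def _tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 3)
        t0 = now

    # ---- stage 1: differential expression (genes/TFs and miRNAs)
    factors = de_mod.estimate_size_factors(inputs.gene_counts)
    if external_de is not None:
        de_genes = external_de
    else:
        de_genes = de_mod.nb_wald_test(
            inputs.gene_counts, inputs.sheet, factors, params.lfc_cut, params.de_p
        )
    factors_m = de_mod.estimate_size_factors(inputs.mirna_counts)
    de_mirnas = de_mod.nb_wald_test(
        inputs.mirna_counts, inputs.sheet, factors_m, params.lfc_cut, params.de_p
    )
    log_expr = de_mod.log_expression(inputs.gene_counts, factors)
    log_expr_m = de_mod.log_expression(inputs.mirna_counts, factors_m)
    _tick("diff_expression")

    # ---- stage 2: differential methylation and pairing
    ann = inputs.probe_ann
    if ann.frame["is_distal"].isna().any():
        ann = dm_mod.derive_distal_flags(ann, inputs.gene_ann)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    diffmeth: list[dm_mod.DiffMethResult] = []
    for direction in ("hypo", "hyper"):
        diffmeth.extend(
            dm_mod.find_diff_meth_probes(
                inputs.beta, inputs.sheet, ann,
                sig_diff=params.sig_diff, p_cut=params.diffmeth_p, direction=direction,
            )
        )
    engine = dm_mod.PairEngine(
        inputs.beta, log_expr, ann.distal_probes(),
        frac=params.mu_frac, min_per_side=params.mu_min_per_side,
    )
    pairs = dm_mod.pair_all(
        diffmeth, ann, inputs.gene_ann, engine,
        k_each_side=params.k_candidate_genes, n_perm=params.n_perm,
        raw_p_cut=params.pair_raw_p, rng=rng,
    )
    paired_probes = sorted({p.probe_id for p in pairs})
    enriched = dm_mod.enrich_motifs(
        paired_probes, engine.distal_ids, inputs.motif_occurrences,
        lower_or=params.motif_lower_or, min_incidence=params.motif_min_incidence,
    )
    occ = inputs.motif_occurrences
    motif_paired = {
        em.motif_id: sorted(set(occ.loc[occ["motif"] == em.motif_id, "probe"]) & set(paired_probes))
        for em in enriched
    }
    mrtfs = dm_mod.nominate_master_regulators(
        enriched, inputs.motif_tf_map, motif_paired, inputs.beta, log_expr,
        p_cut=params.mrtf_p, frac=params.mu_frac, min_per_side=params.mu_min_per_side,
    )
    _tick("diff_methylation")

    # ---- stage 3: network assembly
    tf_ids = set(inputs.interactions["TF-GENE"].frame["source"]) | set(
        inputs.interactions["TF-MIR"].frame["source"]
    )
    nodes = net_mod.assemble_nodes(pairs, de_genes, de_mirnas, mrtfs, tf_ids)
    edges = net_mod.build_network(
        inputs.interactions, nodes, log_expr, log_expr_m, r_p_cut=params.r_p_cut
    )
    summary = net_mod.summarize_network(edges)
    _tick("network_assembly")

    # ---- stage 4: FFL discovery
    ffl_frames = []
    ffl_records: dict[str, list[ffl_mod.FFLRecord]] = {}
    for stratum in ("hypo", "hyper"):
        sub = edges[edges["stratum"] == stratum] if len(edges) else edges
        recs = ffl_mod.enumerate_ffls(sub)
        ffl_records[stratum] = recs
        ffl_frames.append(ffl_mod.ffls_to_frame(recs, stratum))
    ffl_frames = [f for f in ffl_frames if len(f)]
    if ffl_frames:
        ffls = pd.concat(ffl_frames, ignore_index=True)
    else:
        ffls = ffl_mod.ffls_to_frame([], stratum="hypo").iloc[0:0]
    significance = []
    if params.n_random_networks > 0 and len(edges):
        significance = ffl_mod.motif_significance(
            edges, n_random=params.n_random_networks,
            n_swaps_per_edge=params.n_swaps_per_edge, seed=params.seed,
        )
    _tick("ffl_discovery")

    # ---- stage 5: enrichment
    enrichment_results: dict[str, list] = {}
    rollups: dict[str, list] = {}
    if inputs.gene_sets is not None and len(inputs.gene_sets):
        universe = set(inputs.gene_counts.feature_ids)
        strata_queries = {
            "hypo": (nodes.genes["hypo"] | {f.tf_id for f in ffl_records["hypo"]}),
            "hyper": (nodes.genes["hyper"] | {f.tf_id for f in ffl_records["hyper"]}),
        }
        for stratum, query in strata_queries.items():
            query = query & universe
            if not query:
                continue
            res = enr_mod.hypergeom_ora(query, inputs.gene_sets, universe, params.enrichment_fdr)
            enrichment_results[stratum] = res
            if inputs.category_map:
                rollups[stratum] = enr_mod.hallmark_rollup(res, inputs.category_map)
        mirna_nodes = sorted(nodes.mirnas)
        if mirna_nodes:
            res = enr_mod.mirna_target_ora(
                mirna_nodes, inputs.interactions["MIR-GENE"], inputs.gene_sets,
                universe, params.enrichment_fdr,
            )
            enrichment_results["mirna_targets"] = res
    _tick("enrichment")

    # ---- report
    de_up = sorted(de_mod.de_features(de_genes, "up"))
    de_down = sorted(de_mod.de_features(de_genes, "down"))
    report = {
        "params": dataclasses.asdict(params),
        "seed": params.seed,
        "counts": {
            "diffmeth_hypo": sum(1 for d in diffmeth if d.direction == "hypo"),
            "diffmeth_hyper": sum(1 for d in diffmeth if d.direction == "hyper"),
            "pairs": len(pairs),
            "paired_genes_hypo": len(nodes.genes["hypo"]),
            "paired_genes_hyper": len(nodes.genes["hyper"]),
            "de_genes_up": len(de_up),
            "de_genes_down": len(de_down),
            "de_mirnas_up": len(de_mod.de_features(de_mirnas, "up")),
            "de_mirnas_down": len(de_mod.de_features(de_mirnas, "down")),
            "enriched_motifs": len(enriched),
            "mrtfs": len({m.tf_id for m in mrtfs}),
            "edges": _edge_summary_dict(summary),
            "ffls": _ffl_summary_dict(ffls),
        },
        "mrtf_list": sorted({m.tf_id for m in mrtfs}),
        "motif_significance": [dataclasses.asdict(s) for s in significance],
        "enrichment": {
            key: {
                "n_tested": len(res),
                "n_significant": sum(1 for r in res if r.significant),
            }
            for key, res in enrichment_results.items()
        },
        "hallmark_rollup": {
            key: {r.category: r.n_significant for r in rolls}
            for key, rolls in rollups.items()
        },
    }

    results = {
        "diffmeth": diffmeth,
        "pairs": pairs,
        "de_genes": de_genes,
        "de_mirnas": de_mirnas,
        "enriched_motifs": enriched,
        "mrtfs": mrtfs,
        "nodes": nodes,
        "edges": edges,
        "network_summary": summary,
        "ffls": ffls,
        "ffl_records": ffl_records,
        "significance": significance,
        "enrichment": enrichment_results,
        "rollups": rollups,
        "report": report,
    }
    if outdir is not None:
        _write_outputs(Path(outdir), results, timings)
    return results


def _edge_summary_dict(summary: pd.DataFrame) -> dict:
    out: dict[str, dict] = {}
    for row in summary.itertuples(index=False):
        out.setdefault(row.stratum, {})[row.edge_class] = {
            "interactions": int(row.n_interactions),
            "genes": int(row.n_genes),
            "mirnas": int(row.n_mirnas),
            "tfs": int(row.n_tfs),
        }
    return out


def _ffl_summary_dict(ffls: pd.DataFrame) -> dict:
    out: dict[str, dict] = {}
    for t in ffl_mod.FFL_TYPES:
        sub = ffls[ffls["ffl_type"] == t] if len(ffls) else ffls
        out[t] = {
            "total": int(len(sub)),
            "coherent": int((sub["coherence"] == "coherent").sum()) if len(sub) else 0,
            "incoherent": int((sub["coherence"] == "incoherent").sum()) if len(sub) else 0,
            "unclassified": int((sub["coherence"] == "unclassified").sum()) if len(sub) else 0,
        }
    return out


def _write_outputs(outdir: Path, results: dict, timings: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(d) for d in results["diffmeth"]]).to_csv(
        outdir / "diffmeth.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(p) for p in results["pairs"]]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )
    results["de_genes"].to_csv(outdir / "de_genes.tsv", sep="\t")
    results["de_mirnas"].to_csv(outdir / "de_mirnas.tsv", sep="\t")
    pd.DataFrame(
        [
            {k: v for k, v in dataclasses.asdict(e).items() if k != "table"}
            for e in results["enriched_motifs"]
        ]
    ).to_csv(outdir / "motifs_enriched.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(m) for m in results["mrtfs"]]).to_csv(
        outdir / "mrtf.tsv", sep="\t", index=False
    )
    results["edges"].to_csv(outdir / "edges.tsv", sep="\t", index=False)
    results["network_summary"].to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
    results["ffls"].to_csv(outdir / "ffls.tsv", sep="\t", index=False)
    if results["significance"]:
        pd.DataFrame([dataclasses.asdict(s) for s in results["significance"]]).to_csv(
            outdir / "motif_significance.tsv", sep="\t", index=False
        )
    for key, res in results["enrichment"].items():
        enr_mod.enrichment_to_frame(res).to_csv(
            outdir / f"enrichment_{key}.tsv", sep="\t", index=False
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(results["report"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"timings_s": timings}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full workflow from files; writes outputs and the manifest."""
    inputs = load_inputs(config)
    external_de = None
    if config.de_table:
        external_de = de_mod.read_external_de_table(config.de_table)
    results = run_study(inputs, config.params, outdir=outdir, external_de=external_de)
    manifest_path = Path(outdir) / "manifest.json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    manifest["config"] = {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    manifest["input_checksums"] = _checksums(config)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results


def _checksums(config: PipelineConfig) -> dict[str, str]:
    out = {}
    for field in dataclasses.fields(config):
        if field.name == "params":
            continue
        path = getattr(config, field.name)
        if path and Path(path).is_file():
            out[field.name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(inputs: StudyInputs) -> list[dict]:
    """Cross-file consistency checks; returns one pass/fail record each."""
    checks: list[dict] = []

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"check": name, "pass": bool(ok), "detail": detail})

    sheet_samples = set(inputs.sheet.frame["sample"])
    beta_samples = set(inputs.beta.sample_ids)
    rna_samples = set(inputs.gene_counts.sample_ids)
    mir_samples = set(inputs.mirna_counts.sample_ids)
    add("beta_samples_in_sheet", beta_samples <= sheet_samples,
        f"{len(beta_samples - sheet_samples)} beta samples missing from sheet")
    add("rna_samples_in_sheet", rna_samples <= sheet_samples,
        f"{len(rna_samples - sheet_samples)} RNA samples missing from sheet")
    add("mirna_samples_in_sheet", mir_samples <= sheet_samples,
        f"{len(mir_samples - sheet_samples)} miRNA samples missing from sheet")
    shared = beta_samples & rna_samples
    add("beta_rna_overlap", len(shared) >= 10, f"{len(shared)} shared beta/RNA samples")
    for group in ("tumor", "normal"):
        gs = set(inputs.sheet.samples(group))
        add(f"{group}_in_overlap", len(shared & gs) >= 2,
            f"{len(shared & gs)} {group} samples in beta/RNA overlap")
    add("mirna_overlap", len(mir_samples & rna_samples) >= 10,
        f"{len(mir_samples & rna_samples)} shared RNA/miRNA samples")

    ann_probes = set(inputs.probe_ann.frame["probe"])
    add("probes_annotated", set(inputs.beta.probe_ids) <= ann_probes,
        f"{len(set(inputs.beta.probe_ids) - ann_probes)} matrix probes unannotated")
    ann_genes = set(inputs.gene_ann.frame["gene"])
    add("genes_annotated", len(set(inputs.gene_counts.feature_ids) & ann_genes) > 0,
        "no count-matrix feature has a TSS annotation")

    rna_features = set(inputs.gene_counts.feature_ids)
    mir_features = set(inputs.mirna_counts.feature_ids)
    for cls, table in inputs.interactions.items():
        src_kind, tgt_kind = {"TF-GENE": ("rna", "rna"), "TF-MIR": ("rna", "mir"),
                              "MIR-GENE": ("mir", "rna"), "MIR-TF": ("mir", "rna")}[cls]
        src_pool = rna_features if src_kind == "rna" else mir_features
        tgt_pool = rna_features if tgt_kind == "rna" else mir_features
        src_bad = set(table.frame["source"]) - src_pool
        tgt_bad = set(table.frame["target"]) - tgt_pool
        add(f"{cls}_source_kind", not src_bad,
            f"{len(src_bad)} sources not measured on the expected assay")
        add(f"{cls}_target_kind", not tgt_bad,
            f"{len(tgt_bad)} targets not measured on the expected assay")
    return checks
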