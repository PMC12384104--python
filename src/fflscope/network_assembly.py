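"""Signed tripartite network assembly.

Interaction tables (TF->gene, TF->miRNA, miRNA->gene, miRNA->TF) are first
restricted to the differential node sets, then each surviving candidate
edge is signed by the Pearson correlation of its endpoints' expression
(+1 activation / -1 repression) and kept only when the correlation p-value
clears the configured cut. Direction always comes from the database table;
the correlation only supplies the sign.

Networks are built per methylation stratum: gene nodes are the genes of
retained probe-gene pairs, split hypo/hyper by their probe's direction.
TF and miRNA nodes enter a stratum only once they hold a retained edge to
one of its genes; TF-miRNA edges are then evaluated among those stratum
members. Gene/TF expression comes from the RNA matrix, miRNA expression
from the miRNA matrix, and every correlation is computed on the sample
intersection of the two assays involved (dropped when fewer than 10
samples are shared).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import dataclasses
import numpy as np
import pandas as pd
from scipy import stats

from .diff_methylation import MasterRegulator, ProbeGenePair
from .io_formats import EDGE_CLASSES, InteractionTable

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["stratum", "edge_class", "source", "target", "r", "p", "sign"]


@dataclasses.dataclass
class NodeSets:
    """Typed node sets entering the network, genes stratified hypo/hyper."""

    genes: dict[str, set[str]]  # {"hypo": ..., "hyper": ...}
    tfs: set[str]
    mirnas: set[str]


def assemble_nodes(
    pairs: Iterable[ProbeGenePair],
    de_genes: pd.DataFrame,
    de_mirnas: pd.DataFrame,
    mrtfs: Iterable[MasterRegulator],
    tf_ids: Iterable[str],
) -> NodeSets:
    """Build the typed node sets from the upstream stages.

    Gene nodes: genes of retained probe-gene pairs, per stratum. TF nodes:
    differentially expressed members of ``tf_ids`` plus master regulators
    that are themselves DE. miRNA nodes: DE miRNAs. A gene reached via both
    a hypo and a hyper probe lands in both strata (with a warning).
    """
    genes: dict[str, set[str]] = {"hypo": set(), "hyper": set()}
    for p in pairs:
        genes[p.direction].add(p.gene_id)
    both = genes["hypo"] & genes["hyper"]
    if both:
        logger.warning("assemble_nodes: %d genes occur in both strata: %s", len(both), sorted(both)[:5])

    de_status = de_genes["status"]
    de_set = set(de_status.index[de_status != "ns"])
    tfs = (set(tf_ids) & de_set) | {m.tf_id for m in mrtfs if m.tf_id in de_set}
    mirnas = set(de_mirnas.index[de_mirnas["status"] != "ns"])
    if not tfs:
        logger.warning("assemble_nodes: empty TF node set")
    if not mirnas:
        logger.warning("assemble_nodes: empty miRNA node set")
    return NodeSets(genes=genes, tfs=tfs, mirnas=mirnas)


def sign_edges(
    table: InteractionTable,
    source_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    allowed_sources: set[str],
    allowed_targets: set[str],
    r_p_cut: float = 0.05,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Sign candidate edges of one class by Pearson correlation.

    Restricts the table to allowed endpoints present in the expression
    matrices, correlates source vs target over shared samples and keeps
    edges with p < r_p_cut. Returns a frame with columns
    edge_class, source, target, r, p, sign.
    """
    shared = [s for s in source_expr.columns if s in set(target_expr.columns)]
    rows: list[tuple] = []
    n_dropped_short = 0
    cand = table.frame[
        table.frame["source"].isin(allowed_sources & set(source_expr.index))
        & table.frame["target"].isin(allowed_targets & set(target_expr.index))
    ][["source", "target"]].drop_duplicates()
    if len(shared) < min_shared:
        if len(cand):
            logger.warning(
                "sign_edges(%s): only %d shared samples; %d candidate edges dropped",
                table.edge_class, len(shared), len(cand),
            )
        return pd.DataFrame(rows, columns=["edge_class", "source", "target", "r", "p", "sign"])
    for src, tgt in cand.itertuples(index=False):
        x = source_expr.loc[src, shared].to_numpy(dtype=float)
        y = target_expr.loc[tgt, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_shared:
            n_dropped_short += 1
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        if p < r_p_cut and r != 0:
            rows.append((table.edge_class, src, tgt, float(r), float(p), int(np.sign(r))))
    if n_dropped_short:
        logger.warning("sign_edges(%s): %d edges dropped for < %d shared samples",
                       table.edge_class, n_dropped_short, min_shared)
    return pd.DataFrame(rows, columns=["edge_class", "source", "target", "r", "p", "sign"])


def build_network(
    tables: Mapping[str, InteractionTable],
    nodes: NodeSets,
    expr_gene: pd.DataFrame,
    expr_mirna: pd.DataFrame,
    r_p_cut: float = 0.05,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Assemble the signed edge list for both methylation strata.

    Within each stratum, TF->gene and miRNA->gene edges to the stratum's
    genes are signed first; TFs/miRNAs retaining at least one such edge
    constitute the stratum's regulator sets, among which the TF-miRNA
    edges (both orientations) are then signed.
    """
    frames = []
    for stratum in ("hypo", "hyper"):
        sgenes = nodes.genes[stratum]
        if not sgenes or (not nodes.tfs and not nodes.mirnas):
            logger.warning("build_network: empty node class in stratum %s; skipping", stratum)
            continue
        tg = sign_edges(tables["TF-GENE"], expr_gene, expr_gene, nodes.tfs, sgenes,
                        r_p_cut, min_shared)
        mg = sign_edges(tables["MIR-GENE"], expr_mirna, expr_gene, nodes.mirnas, sgenes,
                        r_p_cut, min_shared)
        stratum_tfs = set(tg["source"])
        stratum_mirs = set(mg["source"])
        tm = sign_edges(tables["TF-MIR"], expr_gene, expr_mirna, stratum_tfs, stratum_mirs,
                        r_p_cut, min_shared)
        mt = sign_edges(tables["MIR-TF"], expr_mirna, expr_gene, stratum_mirs, stratum_tfs,
                        r_p_cut, min_shared)
        parts = [f for f in (tg, tm, mg, mt) if len(f)]
        if not parts:
            continue
        part = pd.concat(parts, ignore_index=True)
        part.insert(0, "stratum", stratum)
        frames.append(part)
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[EDGE_COLUMNS]


def summarize_network(edges: pd.DataFrame) -> pd.DataFrame:
    """Per (stratum x edge class) interaction and distinct-node counts.

    Mirrors the eight-cell summary layout of the network tables: for each
    stratum and class, the number of retained interactions and the number
    of distinct genes, miRNAs and TFs involved (by endpoint kind).
    """
    rows = []
    for stratum in ("hypo", "hyper"):
        for cls in EDGE_CLASSES:
            sub = edges[(edges["stratum"] == stratum) & (edges["edge_class"] == cls)] if len(edges) else edges
            src_kind, tgt_kind = {"TF-GENE": ("tf", "gene"), "TF-MIR": ("tf", "mirna"),
                                  "MIR-GENE": ("mirna", "gene"), "MIR-TF": ("mirna", "tf")}[cls]
            counts = {"gene": 0, "mirna": 0, "tf": 0}
            if len(sub):
                counts[src_kind] = sub["source"].nunique()
                counts[tgt_kind] = sub["target"].nunique()
            rows.append(
                {
                    "stratum": stratum,
                    "edge_class": cls,
                    "n_interactions": int(len(sub)),
                    "n_genes": counts["gene"],
                    "n_mirnas": counts["mirna"],
                    "n_tfs": counts["tf"],
                }
            )
    return pd.DataFrame(rows)
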