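"""Three-node feed-forward loop enumeration, classification and scoring.

Loop templates on the signed tripartite network (TF, miRNA, gene):

* TF-mediated:    TF->miRNA, TF->gene, miRNA->gene
* miRNA-mediated: miRNA->TF, miRNA->gene, TF->gene
* composite:      TF<->miRNA mutual pair plus both edges onto the gene

A triple whose TF and miRNA regulate each other mutually (and both hit the
gene) is emitted once, as composite only — never additionally as the two
simple loops — so the three type counts partition the loop set.

Coherence compares the master's direct sign onto the gene with the product
of signs along the indirect master->intermediary->gene path; for composite
loops the rule is evaluated from both masters (coherent/incoherent when the
two evaluations agree, unclassified when they disagree — which can only
happen if the two mutual edges carry opposite signs).

Significance of each loop type is scored against degree- and
class-preserving random networks built by repeated double-edge swaps
within each edge class (signs travel with the source edge).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TF_MEDIATED = "TF-mediated"
MIR_MEDIATED = "miRNA-mediated"
COMPOSITE = "composite"
FFL_TYPES = (TF_MEDIATED, MIR_MEDIATED, COMPOSITE)


@dataclasses.dataclass(frozen=True)
class FFLRecord:
    ffl_type: str
    tf_id: str
    mirna_id: str
    gene_id: str
    sign_tf_gene: int | None
    sign_mir_gene: int | None
    sign_tf_mir: int | None  # TF->miRNA (None for miRNA-mediated loops)
    sign_mir_tf: int | None  # miRNA->TF (None for TF-mediated loops)
    coherence: str = "unclassified"

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.tf_id, self.mirna_id, self.gene_id)


def _sign_maps(edges: pd.DataFrame) -> dict[str, dict[tuple[str, str], int]]:
    maps: dict[str, dict[tuple[str, str], int]] = {c: {} for c in
                                                   ("TF-GENE", "TF-MIR", "MIR-GENE", "MIR-TF")}
    for cls, src, tgt, sign in edges[["edge_class", "source", "target", "sign"]].itertuples(index=False):
        maps[cls][(src, tgt)] = int(sign)
    return maps


def enumerate_ffls(edges: pd.DataFrame) -> list[FFLRecord]:
    """All three-node FFLs present in a signed edge list.

    ``edges`` needs columns edge_class, source, target, sign. Records are
    returned classified, ordered by (type, tf, mirna, gene).
    """
    if len(edges) == 0:
        return []
    maps = _sign_maps(edges)
    tf_genes: dict[str, set[str]] = defaultdict(set)
    tf_mirs: dict[str, set[str]] = defaultdict(set)
    mir_genes: dict[str, set[str]] = defaultdict(set)
    mir_tfs: dict[str, set[str]] = defaultdict(set)
    for (t, g) in maps["TF-GENE"]:
        tf_genes[t].add(g)
    for (t, m) in maps["TF-MIR"]:
        tf_mirs[t].add(m)
    for (m, g) in maps["MIR-GENE"]:
        mir_genes[m].add(g)
    for (m, t) in maps["MIR-TF"]:
        mir_tfs[m].add(t)

    records: list[FFLRecord] = []
    # composite first: mutual TF<->miR pairs claim their triples
    composite_claimed: set[tuple[str, str, str]] = set()
    for t in sorted(tf_mirs):
        for m in sorted(tf_mirs[t]):
            if t not in mir_tfs.get(m, ()):
                continue
            for g in sorted(tf_genes.get(t, set()) & mir_genes.get(m, set())):
                rec = FFLRecord(
                    COMPOSITE, t, m, g,
                    sign_tf_gene=maps["TF-GENE"][(t, g)],
                    sign_mir_gene=maps["MIR-GENE"][(m, g)],
                    sign_tf_mir=maps["TF-MIR"][(t, m)],
                    sign_mir_tf=maps["MIR-TF"][(m, t)],
                )
                records.append(classify_coherence(rec))
                composite_claimed.add((t, m, g))
    for t in sorted(tf_mirs):
        for m in sorted(tf_mirs[t]):
            for g in sorted(tf_genes.get(t, set()) & mir_genes.get(m, set())):
                if (t, m, g) in composite_claimed:
                    continue
                rec = FFLRecord(
                    TF_MEDIATED, t, m, g,
                    sign_tf_gene=maps["TF-GENE"][(t, g)],
                    sign_mir_gene=maps["MIR-GENE"][(m, g)],
                    sign_tf_mir=maps["TF-MIR"][(t, m)],
                    sign_mir_tf=None,
                )
                records.append(classify_coherence(rec))
    for m in sorted(mir_tfs):
        for t in sorted(mir_tfs[m]):
            for g in sorted(mir_genes.get(m, set()) & tf_genes.get(t, set())):
                if (t, m, g) in composite_claimed:
                    continue
                rec = FFLRecord(
                    MIR_MEDIATED, t, m, g,
                    sign_tf_gene=maps["TF-GENE"][(t, g)],
                    sign_mir_gene=maps["MIR-GENE"][(m, g)],
                    sign_tf_mir=None,
                    sign_mir_tf=maps["MIR-TF"][(m, t)],
                )
                records.append(classify_coherence(rec))
    order = {t: i for i, t in enumerate(FFL_TYPES)}
    records.sort(key=lambda r: (order[r.ffl_type], r.tf_id, r.mirna_id, r.gene_id))
    return records


def classify_coherence(ffl: FFLRecord) -> FFLRecord:
    """Label a loop coherent/incoherent by comparing direct and indirect
    regulation signs from the loop's master(s)."""

    def verdict(direct, s1, s2):
        if direct is None or s1 is None or s2 is None:
            return None
        return "coherent" if direct == s1 * s2 else "incoherent"

    if ffl.ffl_type == TF_MEDIATED:
        label = verdict(ffl.sign_tf_gene, ffl.sign_tf_mir, ffl.sign_mir_gene)
    elif ffl.ffl_type == MIR_MEDIATED:
        label = verdict(ffl.sign_mir_gene, ffl.sign_mir_tf, ffl.sign_tf_gene)
    elif ffl.ffl_type == COMPOSITE:
        v_tf = verdict(ffl.sign_tf_gene, ffl.sign_tf_mir, ffl.sign_mir_gene)
        v_mir = verdict(ffl.sign_mir_gene, ffl.sign_mir_tf, ffl.sign_tf_gene)
        label = v_tf if (v_tf is not None and v_tf == v_mir) else None
    else:
        raise ValueError(f"unknown FFL type {ffl.ffl_type!r}")
    return dataclasses.replace(ffl, coherence=label if label is not None else "unclassified")


@dataclasses.dataclass(frozen=True)
class MotifSignificance:
    ffl_type: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_random: int
    seed: int | None


def _swap_class(sub: pd.DataFrame, n_swaps: int, rng: np.random.Generator) -> pd.DataFrame:
    """Degree-preserving double-edge swaps within one edge class.

    Each attempted swap exchanges the targets of two random edges; rejected
    when it would create a duplicate or a self edge. Signs stay attached to
    the (source, old sign) side of each edge.
    """
    src = sub["source"].to_numpy().copy()
    tgt = sub["target"].to_numpy().copy()
    sign = sub["sign"].to_numpy().copy()
    n = len(src)
    if n < 2:
        logger.warning("motif_significance: class %s has < 2 edges; left fixed",
                       sub["edge_class"].iloc[0] if n else "?")
        return sub
    existing = set(zip(src, tgt))
    for a, b in rng.integers(0, n, size=(n_swaps, 2)):
        if a == b:
            continue
        new1, new2 = (src[a], tgt[b]), (src[b], tgt[a])
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        if new1 in existing or new2 in existing:
            continue
        existing.discard((src[a], tgt[a]))
        existing.discard((src[b], tgt[b]))
        tgt[a], tgt[b] = tgt[b], tgt[a]
        existing.add((src[a], tgt[a]))
        existing.add((src[b], tgt[b]))
    out = sub.copy()
    out["source"], out["target"], out["sign"] = src, tgt, sign
    return out


def randomize_network(edges: pd.DataFrame, n_swaps_per_edge: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """One null network: per-class double-edge swaps preserving every
    node's in/out degree within each edge class."""
    parts = []
    for cls in ("TF-GENE", "TF-MIR", "MIR-GENE", "MIR-TF"):
        sub = edges[edges["edge_class"] == cls]
        if len(sub) == 0:
            continue
        parts.append(_swap_class(sub, n_swaps_per_edge * len(sub), rng))
    if not parts:
        return edges.iloc[0:0]
    return pd.concat(parts, ignore_index=True)


def count_by_type(records: Iterable[FFLRecord]) -> dict[str, int]:
    counts = {t: 0 for t in FFL_TYPES}
    for r in records:
        counts[r.ffl_type] += 1
    return counts


def motif_significance(
    edges: pd.DataFrame,
    n_random: int = 1000,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
) -> list[MotifSignificance]:
    """Observed loop counts per type vs the degree-preserving null ensemble.

    Empirical p uses the +1 correction: p = (1 + #{null >= observed})
    / (1 + n_random); z = (observed - mean) / sd when sd > 0, else 0.
    """
    rng = np.random.default_rng(seed)
    observed = count_by_type(enumerate_ffls(edges))
    null_counts = {t: np.zeros(n_random) for t in FFL_TYPES}
    for i in range(n_random):
        null = randomize_network(edges, n_swaps_per_edge, rng)
        for t, c in count_by_type(enumerate_ffls(null)).items():
            null_counts[t][i] = c
    out = []
    for t in FFL_TYPES:
        nulls = null_counts[t]
        mean, sd = float(nulls.mean()), float(nulls.std(ddof=0))
        obs = observed[t]
        z = (obs - mean) / sd if sd > 0 else 0.0
        p = (1.0 + float(np.sum(nulls >= obs))) / (1.0 + n_random)
        out.append(MotifSignificance(t, obs, mean, sd, float(z), p, n_random, seed))
    return out


def ffls_to_frame(records: Iterable[FFLRecord], stratum: str | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "ffl_type": r.ffl_type,
                "tf": r.tf_id,
                "mirna": r.mirna_id,
                "gene": r.gene_id,
                "sign_tf_gene": r.sign_tf_gene,
                "sign_mir_gene": r.sign_mir_gene,
                "sign_tf_mir": r.sign_tf_mir,
                "sign_mir_tf": r.sign_mir_tf,
                "coherence": r.coherence,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["ffl_type", "tf", "mirna", "gene", "sign_tf_gene", "sign_mir_gene",
                 "sign_tf_mir", "sign_mir_tf", "coherence"],
    )
    for col in ("sign_tf_gene", "sign_mir_gene", "sign_tf_mir", "sign_mir_tf"):
        df[col] = df[col].astype("Int64")  # nullable: absent edges stay NA
    if stratum is not None:
        df.insert(0, "stratum", stratum)
    return df
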