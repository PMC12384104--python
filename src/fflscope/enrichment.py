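"""Hypergeometric over-representation analysis and hallmark rollups.

Classical ORA: for a query feature set of size n drawn from a universe of
size N, the overlap k with a gene set of size K is scored by the
upper-tail hypergeometric probability P(X >= k); p-values are adjusted by
Benjamini-Hochberg across all tested sets. The universe is the set of
features measured on the relevant assay (not the genome). miRNA queries
are mapped through a target table first (union of targets). Significant
sets can be rolled up into the eight hallmark process categories.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, InteractionTable, ValidationError

logger = logging.getLogger(__name__)

#: the eight hallmark process categories
HALLMARK_CATEGORIES = (
    "cellular component",
    "development",
    "DNA damage",
    "immune",
    "metabolic",
    "pathway",
    "proliferation",
    "signaling",
)


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    fdr: float
    significant: bool


@dataclasses.dataclass(frozen=True)
class HallmarkRollup:
    category: str
    n_significant: int
    set_ids: tuple[str, ...]


def hypergeom_ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    fdr_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA of ``query`` against every gene set.

    ``query`` must be a subset of ``universe``; sets are intersected with
    the universe before testing and skipped when the intersection is empty.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValidationError("empty query")
    stray = query - universe
    if stray:
        raise ValidationError(f"query features outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    tested: list[tuple[str, int, int]] = []
    for s in sets:
        members = set(s.members) & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        tested.append((s.set_id, k, K))
    if not tested:
        return []
    pvals = [float(stats.hypergeom.sf(k - 1, N, K, n)) for _, k, K in tested]
    fdrs = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(set_id, k, K, n, N, p, float(fdr), bool(fdr < fdr_cut))
        for (set_id, k, K), p, fdr in zip(tested, pvals, fdrs)
    ]


def mirna_target_ora(
    mirnas: Iterable[str],
    target_table: InteractionTable | pd.DataFrame,
    sets: GeneSetCollection,
    universe: Iterable[str],
    fdr_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """ORA of the union of the miRNAs' targets (restricted to the universe)."""
    frame = target_table.frame if isinstance(target_table, InteractionTable) else target_table
    mirnas = set(mirnas)
    targets = set(frame.loc[frame["source"].isin(mirnas), "target"])
    universe = set(universe)
    query = targets & universe
    if not query:
        logger.warning("mirna_target_ora: no targets in universe for %d miRNAs", len(mirnas))
        return []
    return hypergeom_ora(query, sets, universe, fdr_cut)


def hallmark_rollup(
    results: Iterable[EnrichmentResult],
    category_map: Mapping[str, str],
) -> list[HallmarkRollup]:
    """Count significant sets per hallmark process category.

    Unmapped significant sets fall into ``pathway`` with a warning; all
    eight categories are always reported (zero-filled).
    """
    hits: dict[str, list[str]] = {c: [] for c in HALLMARK_CATEGORIES}
    for r in results:
        if not r.significant:
            continue
        cat = category_map.get(r.set_id)
        if cat is None:
            logger.warning("hallmark_rollup: set %s unmapped; counted as 'pathway'", r.set_id)
            cat = "pathway"
        if cat not in hits:
            raise ValidationError(f"unknown hallmark category {cat!r} for set {r.set_id!r}")
        hits[cat].append(r.set_id)
    return [HallmarkRollup(c, len(hits[c]), tuple(hits[c])) for c in HALLMARK_CATEGORIES]


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["set_id", "k", "K", "n", "N", "p", "fdr", "significant"],
    )
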