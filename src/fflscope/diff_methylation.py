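"""Differential methylation at distal probes and its downstream links.

This stage mirrors the enhancer-linking workflow used for 450K arrays:

1. supervised differential methylation of distal probes (one-tailed Welch
   t-test per direction, with both an effect-size floor on the tumor-normal
   mean beta difference and a raw p cutoff);
2. pairing of each significant probe with nearby genes whose expression is
   inversely associated with the probe's methylation, scored against a
   permutation null of random distal probes;
3. motif odds-ratio enrichment among the paired probes;
4. nomination of master-regulator TFs whose expression separates the
   methylated (M) from the unmethylated (U) extreme of each enriched motif.

Defaults are the standard published settings for this analysis: a beta
difference of at least 0.3 at p < 0.01; pair raw p < 0.05 against 10,000
permuted probes; motif 95% CI lower odds bound > 1.1 with incidence >= 10;
M/U groups are the upper/lower 20% of samples by beta with at least 5
samples per side.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    BetaMatrix,
    GeneAnnotation,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: default distance from the nearest TSS beyond which a probe counts as distal
DISTAL_DISTANCE = 2000


@dataclasses.dataclass(frozen=True)
class DiffMethResult:
    probe_id: str
    mean_tumor: float
    mean_normal: float
    delta: float  # tumor - normal mean beta
    p: float
    direction: str  # "hypo" | "hyper"


@dataclasses.dataclass(frozen=True)
class ProbeGenePair:
    probe_id: str
    gene_id: str
    statistic: float  # mean log2 expr (M) - mean log2 expr (U)
    raw_p: float
    distance: int  # |probe position - gene TSS| in bp
    direction: str  # methylation direction of the probe


@dataclasses.dataclass(frozen=True)
class EnrichedMotif:
    motif_id: str
    odds_ratio: float
    ci_lower: float
    incidence: int  # significant (paired) probes bearing the motif
    table: tuple[int, int, int, int]  # (a, b, c, d) before correction


@dataclasses.dataclass(frozen=True)
class MasterRegulator:
    tf_id: str
    motif_id: str
    p: float
    direction: str  # "up" | "down": sign of the M - U median expression difference


def derive_distal_flags(
    probes: ProbeAnnotation, genes: GeneAnnotation, min_distance: int = DISTAL_DISTANCE
) -> ProbeAnnotation:
    """Fill the is_distal flag from gene TSS proximity (> min_distance bp)."""
    out = probes.frame.copy()
    flags = []
    by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.frame.groupby("chrom")}
    for _, row in out.iterrows():
        tss = by_chrom.get(row["chrom"])
        if tss is None or len(tss) == 0:
            flags.append(True)
            continue
        i = np.searchsorted(tss, row["position"])
        cands = tss[max(0, i - 1) : i + 1]
        flags.append(bool(np.abs(cands - row["position"]).min() > min_distance))
    out["is_distal"] = flags
    return ProbeAnnotation(out)


def find_diff_meth_probes(
    beta: BetaMatrix,
    sheet: SampleSheet,
    ann: ProbeAnnotation,
    sig_diff: float = 0.3,
    p_cut: float = 0.01,
    direction: str = "hypo",
) -> list[DiffMethResult]:
    """Distal probes differentially methylated in the requested direction.

    One-tailed Welch t-test (tumor vs normal) per probe; a probe is returned
    when p < p_cut and |delta| >= sig_diff with delta in the requested
    direction. Probes with fewer than 2 non-missing values in either group
    are skipped (counted in the log).
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    tumor = [s for s in sheet.samples("tumor") if s in beta.data.columns]
    normal = [s for s in sheet.samples("normal") if s in beta.data.columns]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >= 2 samples per group")

    distal = [p for p in ann.distal_probes() if p in beta.data.index]
    if not distal:
        return []
    sub = beta.data.loc[distal]
    xt = sub[tumor].to_numpy(dtype=float)
    xn = sub[normal].to_numpy(dtype=float)

    ok = (np.sum(~np.isnan(xt), axis=1) >= 2) & (np.sum(~np.isnan(xn), axis=1) >= 2)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("find_diff_meth_probes: skipped %d probes with < 2 values per group", n_skipped)

    alternative = "less" if direction == "hypo" else "greater"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            xt[ok], xn[ok], axis=1, equal_var=False, nan_policy="omit", alternative=alternative
        )
    mt = np.nanmean(xt[ok], axis=1)
    mn = np.nanmean(xn[ok], axis=1)
    delta = mt - mn

    pvals = np.asarray(res.pvalue, dtype=float)
    if direction == "hypo":
        effect = delta <= -sig_diff
    else:
        effect = delta >= sig_diff
    keep = (pvals < p_cut) & effect & ~np.isnan(pvals)

    ids = np.asarray(distal)[ok]
    out = [
        DiffMethResult(ids[i], float(mt[i]), float(mn[i]), float(delta[i]), float(pvals[i]), direction)
        for i in np.flatnonzero(keep)
    ]
    return out


def candidate_genes(
    probe_id: str,
    ann: ProbeAnnotation,
    genes: GeneAnnotation,
    k_each_side: int = 10,
) -> list[str]:
    """The k nearest genes by |TSS - probe position| on each side of the probe.

    Genes with TSS strictly left of the probe count as upstream; TSS at or
    right of the probe as downstream. Returned ordered by distance (ties by
    gene id); fewer genes near chromosome ends. Empty (and logged) when the
    chromosome carries no annotated gene.
    """
    row = ann.frame.loc[ann.frame["probe"] == probe_id]
    if row.empty:
        raise ValidationError(f"unknown probe {probe_id!r}")
    chrom = row["chrom"].iloc[0]
    pos = int(row["position"].iloc[0])
    g = genes.frame[genes.frame["chrom"] == chrom]
    if g.empty:
        logger.warning("candidate_genes: no gene on chromosome %s for probe %s", chrom, probe_id)
        return []
    dist = (g["tss"] - pos).to_numpy()
    frame = pd.DataFrame({"gene": g["gene"].to_numpy(), "dist": np.abs(dist), "side": dist < 0})
    picks = []
    for side in (True, False):
        sub = frame[frame["side"] == side].sort_values(["dist", "gene"], kind="stable")
        picks.append(sub.head(k_each_side))
    out = pd.concat(picks).sort_values(["dist", "gene"], kind="stable")
    return list(out["gene"])


def mu_groups(
    beta_row: pd.Series, frac: float = 0.2, min_per_side: int = 5
) -> tuple[list[str], list[str]]:
    """Split samples into methylated (M, upper ``frac`` by beta) and
    unmethylated (U, lower ``frac``) extremes; ties broken by sample order.

    Raises ValidationError when the two sides would overlap.
    """
    vals = beta_row.dropna()
    n = len(vals)
    k = max(min_per_side, int(round(frac * n)))
    if 2 * k > n:
        raise ValidationError(f"too few samples ({n}) for M/U split of {k} per side")
    order = np.argsort(vals.to_numpy(), kind="stable")
    samples = vals.index.to_numpy()
    u = list(samples[order[:k]])
    m = list(samples[order[-k:]])
    return m, u


class PairEngine:
    """Vectorized machinery for probe-gene pairing.

    For every distal probe (restricted to samples shared between the beta
    and expression matrices) a fixed M/U contrast vector is precomputed, so
    that the pairing statistic of any (probe, gene) and the full null
    distribution of a gene over all distal probes are single matrix-vector
    products.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        log_expr: pd.DataFrame,
        distal_probe_ids: Sequence[str],
        frac: float = 0.2,
        min_per_side: int = 5,
    ) -> None:
        shared = [s for s in beta.sample_ids if s in set(log_expr.columns)]
        if len(shared) < 10:
            raise ValidationError(f"only {len(shared)} shared samples between beta and expression")
        self.samples = shared
        self.distal_ids = [p for p in distal_probe_ids if p in beta.data.index]
        self.index_of = {p: i for i, p in enumerate(self.distal_ids)}
        self.expr = log_expr[shared]

        bmat = beta.data.loc[self.distal_ids, shared].to_numpy(dtype=float)
        n_probes, n_samples = bmat.shape
        contrast = np.zeros((n_probes, n_samples))
        self.usable = np.ones(n_probes, dtype=bool)
        for i in range(n_probes):
            row = bmat[i]
            notna = np.flatnonzero(~np.isnan(row))
            n = len(notna)
            k = max(min_per_side, int(round(frac * n)))
            if 2 * k > n:
                self.usable[i] = False
                continue
            order = notna[np.argsort(row[notna], kind="stable")]
            contrast[i, order[-k:]] = 1.0 / k   # M group
            contrast[i, order[:k]] = -1.0 / k   # U group
        self.contrast = contrast

    def null_statistics(self, gene_id: str) -> np.ndarray:
        """Pairing statistic of ``gene_id`` against every usable distal probe."""
        e = self.expr.loc[gene_id].to_numpy(dtype=float)
        return self.contrast[self.usable] @ e

    def statistic(self, probe_id: str, gene_id: str) -> float:
        i = self.index_of[probe_id]
        if not self.usable[i]:
            raise ValidationError(f"probe {probe_id!r} has too few samples for an M/U split")
        e = self.expr.loc[gene_id].to_numpy(dtype=float)
        return float(self.contrast[i] @ e)


def pair_probe_gene(
    probe: DiffMethResult,
    gene_id: str,
    engine: PairEngine,
    distance: int,
    n_perm: int = 10000,
    raw_p_cut: float = 0.05,
    rng: np.random.Generator | None = None,
    null_stats: np.ndarray | None = None,
) -> ProbeGenePair | None:
    """Test one probe-gene link against the random-distal-probe null.

    The statistic is the mean log2-expression difference between the M and U
    sample groups of the probe; the empirical raw p is the (+1-corrected)
    fraction of ``n_perm`` random distal probes whose statistic is at least
    as extreme in the anti-correlated (negative) direction. Returns None
    when the pair is not retained.
    """
    rng = rng if rng is not None else np.random.default_rng()
    expr_row = engine.expr.loc[gene_id]
    if expr_row.nunique() <= 1:
        logger.warning("pair_probe_gene: constant expression for %s; pair skipped", gene_id)
        return None
    obs = engine.statistic(probe.probe_id, gene_id)
    if null_stats is None:
        null_stats = engine.null_statistics(gene_id)
    draws = null_stats[rng.integers(0, len(null_stats), size=n_perm)]
    raw_p = (1.0 + np.sum(draws <= obs)) / (1.0 + n_perm)
    if raw_p >= raw_p_cut:
        return None
    return ProbeGenePair(probe.probe_id, gene_id, obs, float(raw_p), distance, probe.direction)


def pair_all(
    diffmeth: Iterable[DiffMethResult],
    ann: ProbeAnnotation,
    genes: GeneAnnotation,
    engine: PairEngine,
    k_each_side: int = 10,
    n_perm: int = 10000,
    raw_p_cut: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[ProbeGenePair]:
    """Pair every significant probe with its candidate genes.

    Null statistics are computed once per gene and shared across the probes
    that test it.
    """
    rng = rng if rng is not None else np.random.default_rng()
    probe_pos = dict(zip(ann.frame["probe"], ann.frame["position"]))
    gene_tss = dict(zip(genes.frame["gene"], genes.frame["tss"]))
    null_cache: dict[str, np.ndarray] = {}
    pairs: list[ProbeGenePair] = []
    for dm in diffmeth:
        for gid in candidate_genes(dm.probe_id, ann, genes, k_each_side):
            if gid not in engine.expr.index:
                continue
            if gid not in null_cache:
                null_cache[gid] = engine.null_statistics(gid)
            pair = pair_probe_gene(
                dm,
                gid,
                engine,
                distance=abs(probe_pos[dm.probe_id] - gene_tss[gid]),
                n_perm=n_perm,
                raw_p_cut=raw_p_cut,
                rng=rng,
                null_stats=null_cache[gid],
            )
            if pair is not None:
                pairs.append(pair)
    return pairs


def enrich_motifs(
    paired_probes: Iterable[str],
    all_distal: Iterable[str],
    motif_occurrences: pd.DataFrame,
    lower_or: float = 1.1,
    min_incidence: int = 10,
) -> list[EnrichedMotif]:
    """Motifs over-represented among paired probes vs the distal background.

    Per motif a 2x2 table of motif presence x paired-set membership is
    built over the distal universe (background = distal probes NOT in the
    paired set); OR = (a/b)/(c/d) with a Haldane-Anscombe 0.5 correction
    when any cell is zero, and a normal-approximation 95% CI on log OR. A
    motif is retained when the CI lower bound exceeds ``lower_or`` and its
    incidence a (paired probes bearing it) is at least ``min_incidence``.
    """
    paired = set(paired_probes)
    distal = set(all_distal)
    if not paired <= distal:
        raise ValidationError("paired probes must be a subset of the distal universe")
    background = distal - paired
    out: list[EnrichedMotif] = []
    occ = motif_occurrences[motif_occurrences["probe"].isin(distal)]
    for motif, grp in occ.groupby("motif", sort=True):
        probes = set(grp["probe"])
        a = len(probes & paired)
        c = len(probes & background)
        if a + c == 0:
            continue
        b = len(paired) - a
        d = len(background) - c
        aa, bb, cc, dd = (a, b, c, d)
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (aa / bb) / (cc / dd)
        se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
        ci_lower = float(np.exp(np.log(odds) - 1.959963984540054 * se))
        if ci_lower > lower_or and a >= min_incidence:
            out.append(EnrichedMotif(str(motif), float(odds), ci_lower, a, (a, b, c, d)))
    return out


def nominate_master_regulators(
    enriched: Iterable[EnrichedMotif],
    motif_tf_map: pd.DataFrame,
    motif_paired_probes: Mapping[str, Sequence[str]],
    beta: BetaMatrix,
    log_expr: pd.DataFrame,
    p_cut: float = 0.05,
    frac: float = 0.2,
    min_per_side: int = 5,
) -> list[MasterRegulator]:
    """Master-regulator TFs per enriched motif.

    The average beta over the motif's paired probes defines M/U extremes;
    each candidate TF of the motif (per the motif->TF family table) is
    tested by a one-sided rank-sum of its expression between M and U (both
    directions, smaller p reported). Direction ``down`` means expression is
    lower in the methylated extreme (anti-correlated with methylation).
    """
    shared = [s for s in beta.sample_ids if s in set(log_expr.columns)]
    candidates = motif_tf_map.groupby("motif")["tf"].apply(list).to_dict()
    out: list[MasterRegulator] = []
    for em in enriched:
        probes = [p for p in motif_paired_probes.get(em.motif_id, []) if p in beta.data.index]
        if not probes:
            continue
        avg_beta = beta.data.loc[probes, shared].mean(axis=0, skipna=True)
        m_samples, u_samples = mu_groups(avg_beta, frac=frac, min_per_side=min_per_side)
        for tf in candidates.get(em.motif_id, []):
            if tf not in log_expr.index:
                logger.warning("nominate_master_regulators: TF %s absent from expression; skipped", tf)
                continue
            xm = log_expr.loc[tf, m_samples].to_numpy(dtype=float)
            xu = log_expr.loc[tf, u_samples].to_numpy(dtype=float)
            if np.all(xm == xm[0]) and np.all(xu == xu[0]) and xm[0] == xu[0]:
                continue
            p_down = stats.mannwhitneyu(xm, xu, alternative="less").pvalue
            p_up = stats.mannwhitneyu(xm, xu, alternative="greater").pvalue
            if p_down <= p_up:
                p, direction = p_down, "down"
            else:
                p, direction = p_up, "up"
            if p < p_cut:
                out.append(MasterRegulator(tf, em.motif_id, float(p), direction))
    return out
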