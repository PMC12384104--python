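"""Synthetic study generator with planted ground truth.

Emits every input the pipeline consumes — beta matrix, gene and miRNA
count matrices, sample sheet, probe/gene annotations, motif tables,
interaction tables, gene sets — together with an answer key
(:class:`SyntheticTruth`) listing the planted differentially methylated
probes, probe-gene pairs, enriched motifs, master-regulator TFs,
differential features and feed-forward loops.

Model sketch
------------
* Beta values are simulated on the logit scale (Gaussian noise, inverse
  logit, clipped to [0.01, 0.99]); planted probes have their tumor group
  mean shifted by +-delta_beta on the probability scale.
* Counts are negative binomial with gene-wise log-normal dispersion and
  log-uniform library sizes spanning a 4-fold range.
* Each planted probe-gene pair's gene receives a monotone decreasing
  log-linear link to its probe's beta, so methylation up implies
  expression down both across and within groups.
* Planted feed-forward loop members share multivariate-normal biological
  noise whose pairwise correlation signs equal the planted edge signs;
  group (tumor/normal) directions of loop TFs and miRNAs are chosen so the
  group-structure covariance reinforces the master-path signs, and loop
  genes use a slightly smaller methylation shift plus a larger biological
  noise so that the one group-misaligned edge of incoherent loops still
  carries its planted correlation sign.
* Planted motifs land on planted (hypomethylated) paired probes with a
  configured odds over the distal background; each maps to a planted
  master-regulator TF that is itself differentially expressed.

Every random draw comes from a named child stream of the single config
seed, so identical (config, seed) reruns are byte-identical and a change
in one component's parameters does not reshuffle the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import OrderedDict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ffl_discovery import COMPOSITE, MIR_MEDIATED, TF_MEDIATED
from .io_formats import (
    BetaMatrix,
    CountMatrix,
    GeneAnnotation,
    GeneSet,
    GeneSetCollection,
    InteractionTable,
    ProbeAnnotation,
    SampleSheet,
    write_category_map,
    write_gene_annotation,
    write_gmt,
    write_interactions,
    write_matrix,
    write_motif_occurrences,
    write_motif_tf_map,
    write_probe_annotation,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The simulation config is internally infeasible."""


def _default_ffls() -> "OrderedDict[tuple[str, str], int]":
    return OrderedDict(
        [
            ((TF_MEDIATED, "coherent"), 3),
            ((TF_MEDIATED, "incoherent"), 3),
            ((MIR_MEDIATED, "coherent"), 3),
            ((MIR_MEDIATED, "incoherent"), 3),
            ((COMPOSITE, "coherent"), 1),
            ((COMPOSITE, "incoherent"), 1),
        ]
    )


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions. Defaults mirror the cohort scale of the motivating
    TCGA basal-like analysis (134/84 methylation+RNA samples, 129/56 miRNA
    samples, 99 hypo- and 53 hypermethylated probe-gene pairs) at a desk-
    scale feature count."""

    n_tumor: int = 134
    n_normal: int = 84
    n_tumor_mirna: int = 129
    n_normal_mirna: int = 56

    n_probes: int = 2000
    n_genes: int = 800
    n_tfs: int = 60
    n_mirnas: int = 200

    n_hypo_pairs: int = 99
    n_hyper_pairs: int = 53
    delta_beta: float = 0.5
    beta_logit_sd: float = 0.5

    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    libsize_fold_range: float = 4.0
    planted_log2fc: float = 1.5
    n_de_genes: int = 80
    n_de_tfs: int = 20
    n_de_mirnas: int = 60
    bio_sd: float = 0.35

    n_ffls: "OrderedDict[tuple[str, str], int]" = dataclasses.field(default_factory=_default_ffls)
    ffl_bio_sd: float = 1.0
    ffl_delta_beta: float = 0.4
    edge_rho: float = 0.45
    meth_slope: float = 2.0

    n_planted_motifs: int = 3
    motif_odds: float = 8.0
    motif_bg_rate: float = 0.03
    n_bg_motifs: int = 10

    n_decoy_edges: int = 120
    n_gene_sets: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_tumor", "n_normal", "n_probes", "n_genes", "n_mirnas", "n_tfs"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be >= 1")
        if not (0.0 <= self.delta_beta < 1.0):
            raise ConfigurationError("delta_beta must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_tumor_mirna > self.n_tumor or self.n_normal_mirna > self.n_normal:
            raise ConfigurationError("miRNA cohort cannot exceed the main cohort")
        n_loops = sum(self.n_ffls.values())
        if self.n_hypo_pairs + self.n_hyper_pairs + n_loops > self.n_probes:
            raise ConfigurationError("more planted pairs/loops than probes")
        if (self.n_hypo_pairs + self.n_hyper_pairs + n_loops + self.n_de_genes
                > self.n_genes):
            raise ConfigurationError("more planted pair/loop/DE genes than genes")
        if self.n_de_tfs > self.n_tfs or self.n_de_mirnas > self.n_mirnas:
            raise ConfigurationError("more planted DE TFs/miRNAs than TFs/miRNAs")
        if n_loops > min(self.n_tfs, self.n_mirnas):
            raise ConfigurationError("more planted loops than TFs or miRNAs")
        if n_loops + self.n_planted_motifs > self.n_de_tfs:
            raise ConfigurationError("n_de_tfs too small for planted loops + motifs")
        if n_loops > self.n_de_mirnas:
            raise ConfigurationError("n_de_mirnas too small for planted loops")


@dataclasses.dataclass
class PlantedFFL:
    ffl_type: str
    coherence: str
    tf: str
    mirna: str
    gene: str
    sign_tf_gene: int
    sign_mir_gene: int
    sign_tf_mir: int | None
    sign_mir_tf: int | None

    def key(self) -> tuple[str, str, str, str]:
        return (self.ffl_type, self.tf, self.mirna, self.gene)


@dataclasses.dataclass
class SyntheticTruth:
    """Answer key for a simulated study."""

    probes: dict[str, dict]  # probe -> {direction, true_delta}
    pairs: list[tuple[str, str]]  # (probe, gene)
    motifs: list[str]
    mrtfs: list[dict]  # {motif, tf, direction}
    de_genes: dict[str, float]  # feature (gene or TF) -> true log2fc
    de_mirnas: dict[str, float]
    ffls: list[PlantedFFL]
    universe: dict[str, list[str]]  # probes / genes / tfs / mirnas ids

    def to_json(self) -> dict:
        return {
            "probes": self.probes,
            "pairs": [list(p) for p in self.pairs],
            "motifs": self.motifs,
            "mrtfs": self.mrtfs,
            "de_genes": self.de_genes,
            "de_mirnas": self.de_mirnas,
            "ffls": [dataclasses.asdict(f) for f in self.ffls],
            "universe": self.universe,
        }


@dataclasses.dataclass
class StudyInputs:
    """The full input bundle the pipeline consumes."""

    beta: BetaMatrix
    gene_counts: CountMatrix
    mirna_counts: CountMatrix
    sheet: SampleSheet
    probe_ann: ProbeAnnotation
    gene_ann: GeneAnnotation
    motif_occurrences: pd.DataFrame
    motif_tf_map: pd.DataFrame
    interactions: dict[str, InteractionTable]
    gene_sets: GeneSetCollection
    category_map: dict[str, str]


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")
_CHROM_LEN = 50_000_000


def simulate_study(config: SimulationConfig) -> tuple[StudyInputs, SyntheticTruth]:
    """Generate the full input bundle plus its answer key."""
    cfg = config
    rngs = _streams(cfg.seed, [
        "layout", "beta", "expr", "mirna", "libsize", "dispersion",
        "motifs", "edges", "genesets",
    ])

    # ---------------- identifiers and sample sheet
    tumor = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    normal = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumor + normal
    mirna_samples = tumor[: cfg.n_tumor_mirna] + normal[: cfg.n_normal_mirna]
    sheet = SampleSheet(pd.DataFrame({
        "sample": samples,
        "group": ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
    }))
    is_tumor = np.array([1.0] * cfg.n_tumor + [0.0] * cfg.n_normal)

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    tfs = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    mirs = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    rna_features = genes + tfs
    probes = [f"cg{i + 1:05d}" for i in range(cfg.n_probes)]

    # ---------------- planted assignments
    rl = rngs["layout"]
    loop_specs: list[tuple[str, str]] = []
    for (ftype, coh), n in cfg.n_ffls.items():
        loop_specs.extend([(ftype, coh)] * n)
    n_loops = len(loop_specs)

    gene_pool = list(rl.permutation(genes))
    hypo_genes = gene_pool[: cfg.n_hypo_pairs]
    hyper_genes = gene_pool[cfg.n_hypo_pairs : cfg.n_hypo_pairs + cfg.n_hyper_pairs]
    ffl_genes = gene_pool[
        cfg.n_hypo_pairs + cfg.n_hyper_pairs : cfg.n_hypo_pairs + cfg.n_hyper_pairs + n_loops
    ]
    tf_pool = list(rl.permutation(tfs))
    ffl_tfs = tf_pool[:n_loops]
    mrtf_tfs = tf_pool[n_loops : n_loops + cfg.n_planted_motifs]
    extra_de_tfs = tf_pool[n_loops + cfg.n_planted_motifs : cfg.n_de_tfs]
    mir_pool = list(rl.permutation(mirs))
    ffl_mirs = mir_pool[:n_loops]
    extra_de_mirs = mir_pool[n_loops : cfg.n_de_mirnas]
    extra_de_genes = gene_pool[
        cfg.n_hypo_pairs + cfg.n_hyper_pairs + n_loops :
        cfg.n_hypo_pairs + cfg.n_hyper_pairs + n_loops + cfg.n_de_genes
    ]
    assert len(extra_de_genes) == cfg.n_de_genes  # guaranteed by config validation

    # ---------------- planted FFL wiring (signs, directions)
    planted_ffls: list[PlantedFFL] = []
    de_dir: dict[str, int] = {}  # feature -> +1 up / -1 down
    ffl_gene_dir: dict[str, int] = {}
    for i, (ftype, coh) in enumerate(loop_specs):
        t, m, g = ffl_tfs[i], ffl_mirs[i], ffl_genes[i]
        pm = 1 if coh == "coherent" else -1
        s_tm = int(rl.choice([-1, 1]))  # TF<->miR pair sign
        s_tg = int(rl.choice([-1, 1]))
        s_mg = pm * s_tm * s_tg  # enforce coherence class
        d_t = int(rl.choice([-1, 1]))
        d_m = s_tm * d_t  # align TF-miR edge with the group structure
        if ftype == MIR_MEDIATED:
            d_g = s_mg * d_m  # align the master (miRNA) -> gene edge
        else:
            d_g = s_tg * d_t  # align the TF -> gene edge
        de_dir[t] = d_t
        de_dir[m] = d_m
        ffl_gene_dir[g] = d_g
        planted_ffls.append(PlantedFFL(
            ftype, coh, t, m, g,
            sign_tf_gene=s_tg,
            sign_mir_gene=s_mg,
            sign_tf_mir=s_tm if ftype in (TF_MEDIATED, COMPOSITE) else None,
            sign_mir_tf=s_tm if ftype in (MIR_MEDIATED, COMPOSITE) else None,
        ))
    for i, f in enumerate(mrtf_tfs + extra_de_tfs + extra_de_genes):
        de_dir[f] = 1 if i % 2 == 0 else -1
    for i, f in enumerate(extra_de_mirs):
        de_dir[f] = 1 if i % 2 == 0 else -1

    # ---------------- genome layout: gene TSS, probe positions
    gene_chrom = rl.integers(0, len(_CHROMS), size=len(rna_features))
    gene_tss = rl.integers(10_000, _CHROM_LEN, size=len(rna_features))
    gene_strand = rl.choice(["+", "-"], size=len(rna_features))
    gene_ann = GeneAnnotation(pd.DataFrame({
        "gene": rna_features,
        "chrom": [_CHROMS[c] for c in gene_chrom],
        "tss": gene_tss,
        "strand": gene_strand,
    }))
    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in gene_ann.frame.groupby("chrom")
    }

    def _distal_ok(chrom: str, pos: int) -> bool:
        tss = tss_by_chrom[chrom]
        i = np.searchsorted(tss, pos)
        near = tss[max(0, i - 1) : i + 1]
        return pos >= 0 and (len(near) == 0 or np.abs(near - pos).min() > 2000)

    gene_pos = dict(zip(rna_features, zip((_CHROMS[c] for c in gene_chrom), gene_tss)))
    paired_gene_list = hypo_genes + hyper_genes + ffl_genes
    probe_chrom: list[str] = []
    probe_pos: list[int] = []
    pairs: list[tuple[str, str]] = []
    for j, g in enumerate(paired_gene_list):
        chrom, tss = gene_pos[g]
        for _ in range(200):
            offset = int(rl.integers(5_000, 300_000)) * int(rl.choice([-1, 1]))
            pos = tss + offset
            if 0 <= pos < _CHROM_LEN and _distal_ok(chrom, pos):
                break
        else:  # pragma: no cover - pathological layout
            raise ConfigurationError(f"could not place a distal probe near {g}")
        probe_chrom.append(chrom)
        probe_pos.append(pos)
        pairs.append((probes[j], g))
    n_planted_probes = len(paired_gene_list)
    for j in range(n_planted_probes, cfg.n_probes):
        chrom = _CHROMS[int(rl.integers(0, len(_CHROMS)))]
        pos = int(rl.integers(0, _CHROM_LEN))
        probe_chrom.append(chrom)
        probe_pos.append(pos)
    is_distal = [_distal_ok(c, p) for c, p in zip(probe_chrom, probe_pos)]
    is_distal[:n_planted_probes] = [True] * n_planted_probes
    probe_ann = ProbeAnnotation(pd.DataFrame({
        "probe": probes, "chrom": probe_chrom, "position": probe_pos, "is_distal": is_distal,
    }))

    # ---------------- beta matrix
    rb = rngs["beta"]
    probe_dir = np.zeros(cfg.n_probes)  # -1 hypo / +1 hyper / 0 background
    probe_delta = np.zeros(cfg.n_probes)
    n_hypo, n_hyper = cfg.n_hypo_pairs, cfg.n_hyper_pairs
    probe_dir[:n_hypo] = -1
    probe_delta[:n_hypo] = cfg.delta_beta
    probe_dir[n_hypo : n_hypo + n_hyper] = 1
    probe_delta[n_hypo : n_hypo + n_hyper] = cfg.delta_beta
    for i, g in enumerate(ffl_genes):
        j = n_hypo + n_hyper + i
        probe_dir[j] = -ffl_gene_dir[g]  # gene up in tumor -> hypomethylated probe
        probe_delta[j] = cfg.ffl_delta_beta

    base = np.where(
        probe_dir == 0,
        rb.uniform(0.15, 0.85, size=cfg.n_probes),
        np.where(
            probe_dir < 0,
            rb.uniform(0.55, 0.95, size=cfg.n_probes),
            rb.uniform(0.15, 0.45, size=cfg.n_probes),
        ),
    )
    # keep shifted means inside (0.05, 0.95)
    base = np.where(probe_dir < 0, np.clip(base, probe_delta + 0.05, 0.95), base)
    base = np.where(probe_dir > 0, np.clip(base, 0.05, 0.95 - probe_delta), base)
    mean_mat = np.tile(base[:, None], (1, len(samples)))
    shift = probe_dir * probe_delta
    mean_mat[:, : cfg.n_tumor] = np.clip(
        (base + shift)[:, None] * np.ones((1, cfg.n_tumor)), 0.02, 0.98
    )
    noise = rb.normal(0.0, cfg.beta_logit_sd, size=mean_mat.shape)
    beta_vals = np.clip(_sigmoid(_logit(np.clip(mean_mat, 0.02, 0.98)) + noise), 0.01, 0.99)
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probes, columns=samples))

    # ---------------- expression (RNA: genes + TFs)
    re_, rm = rngs["expr"], rngs["mirna"]
    ln2 = np.log(2.0)
    n_rna = len(rna_features)
    base_mean = np.exp(re_.uniform(np.log(cfg.nb_mean / 4.0), np.log(cfg.nb_mean * 8.0), size=n_rna))
    logmu = np.log(base_mean)[:, None] + np.zeros((n_rna, len(samples)))
    rna_index = {f: i for i, f in enumerate(rna_features)}
    for f, d in de_dir.items():
        if f in rna_index:
            logmu[rna_index[f]] += ln2 * cfg.planted_log2fc * d * is_tumor

    # methylation link for every paired gene (incl. loop genes)
    probe_of_gene = {g: p for p, g in pairs}
    for g in paired_gene_list:
        b = beta.data.loc[probe_of_gene[g]].to_numpy()
        logmu[rna_index[g]] += -cfg.meth_slope * (b - b.mean())

    # biological noise: iid background, shared MVN for loop members
    noise_rna = re_.normal(0.0, cfg.bio_sd, size=logmu.shape)
    n_mir = len(mirs)
    mir_index = {f: i for i, f in enumerate(mirs)}
    base_mean_m = np.exp(rm.uniform(np.log(cfg.nb_mean / 4.0), np.log(cfg.nb_mean * 8.0), size=n_mir))
    logmu_m = np.log(base_mean_m)[:, None] + np.zeros((n_mir, len(samples)))
    for f, d in de_dir.items():
        if f in mir_index:
            logmu_m[mir_index[f]] += ln2 * cfg.planted_log2fc * d * is_tumor
    noise_mir = rm.normal(0.0, cfg.bio_sd, size=logmu_m.shape)

    for f in planted_ffls:
        s_tm = f.sign_tf_mir if f.sign_tf_mir is not None else f.sign_mir_tf
        rho = cfg.edge_rho
        corr = np.array([
            [1.0, rho * s_tm, rho * f.sign_tf_gene],
            [rho * s_tm, 1.0, rho * f.sign_mir_gene],
            [rho * f.sign_tf_gene, rho * f.sign_mir_gene, 1.0],
        ])
        chol = np.linalg.cholesky(corr)
        z = re_.normal(size=(3, len(samples)))
        shared = cfg.ffl_bio_sd * (chol @ z)
        noise_rna[rna_index[f.tf]] = shared[0]
        noise_mir[mir_index[f.mirna]] = shared[1]
        noise_rna[rna_index[f.gene]] = shared[2]

    logmu += noise_rna
    logmu_m += noise_mir

    # ---------------- NB sampling with library sizes
    rl_lib, rd = rngs["libsize"], rngs["dispersion"]
    half = np.log(np.sqrt(cfg.libsize_fold_range))
    sf = np.exp(rl_lib.uniform(-half, half, size=len(samples)))
    sf_m = np.exp(rl_lib.uniform(-half, half, size=len(mirna_samples)))
    alpha = np.exp(rd.normal(np.log(cfg.nb_dispersion), 0.5, size=n_rna))
    alpha_m = np.exp(rd.normal(np.log(cfg.nb_dispersion), 0.5, size=n_mir))

    mu = sf[None, :] * np.exp(logmu)
    r = (1.0 / alpha)[:, None]
    gene_counts = CountMatrix(pd.DataFrame(
        re_.negative_binomial(r, r / (r + mu)), index=rna_features, columns=samples,
    ))
    mir_cols = [samples.index(s) for s in mirna_samples]
    mu_m = sf_m[None, :] * np.exp(logmu_m[:, mir_cols])
    r_m = (1.0 / alpha_m)[:, None]
    mirna_counts = CountMatrix(pd.DataFrame(
        rm.negative_binomial(r_m, r_m / (r_m + mu_m)), index=mirs, columns=mirna_samples,
    ))

    # ---------------- motif occurrences and motif -> TF map
    rmo = rngs["motifs"]
    planted_motifs = [f"MOTIF{i + 1:02d}" for i in range(cfg.n_planted_motifs)]
    bg_motifs = [f"BGMOT{i + 1:02d}" for i in range(cfg.n_bg_motifs)]
    hypo_probe_ids = [probes[i] for i in range(n_hypo)]
    distal_ids = [p for p, d in zip(probes, is_distal) if d]
    bg = cfg.motif_bg_rate
    fg = cfg.motif_odds * bg / (1.0 - bg + cfg.motif_odds * bg)
    occ_rows: list[tuple[str, str]] = []
    for mo in planted_motifs:
        for p in hypo_probe_ids:
            if rmo.random() < fg:
                occ_rows.append((mo, p))
        for p in distal_ids:
            if p not in set(hypo_probe_ids) and rmo.random() < bg:
                occ_rows.append((mo, p))
    for mo in bg_motifs:
        for p in distal_ids:
            if rmo.random() < bg:
                occ_rows.append((mo, p))
    motif_occurrences = pd.DataFrame(occ_rows, columns=["motif", "probe"])
    map_rows = []
    mrtf_truth = []
    for mo, tf in zip(planted_motifs, mrtf_tfs):
        map_rows.append((mo, tf))
        decoy_tf = tf_pool[-1 - len(map_rows)]  # a non-DE family member
        if decoy_tf not in de_dir:
            map_rows.append((mo, decoy_tf))
        # motifs sit on hypomethylated probes: M extreme ~ normal samples,
        # so an up-in-tumor TF reads as 'down' across the M-U contrast
        mrtf_truth.append({"motif": mo, "tf": tf,
                           "direction": "down" if de_dir[tf] > 0 else "up"})
    for mo in bg_motifs:
        map_rows.append((mo, tf_pool[int(rmo.integers(0, len(tf_pool)))]))
    motif_tf_map = pd.DataFrame(map_rows, columns=["motif", "tf"]).drop_duplicates()

    # ---------------- interaction tables
    red = rngs["edges"]
    planted_edges: dict[str, set[tuple[str, str]]] = {c: set() for c in
                                                      ("TF-GENE", "TF-MIR", "MIR-GENE", "MIR-TF")}
    for f in planted_ffls:
        planted_edges["TF-GENE"].add((f.tf, f.gene))
        planted_edges["MIR-GENE"].add((f.mirna, f.gene))
        if f.sign_tf_mir is not None:
            planted_edges["TF-MIR"].add((f.tf, f.mirna))
        if f.sign_mir_tf is not None:
            planted_edges["MIR-TF"].add((f.mirna, f.tf))

    def _decoys(cls: str, sources: list[str], targets: list[str],
                forbidden: set[tuple[str, str]]) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        guard = 0
        while len(out) < cfg.n_decoy_edges and guard < 50 * cfg.n_decoy_edges:
            guard += 1
            s = sources[int(red.integers(0, len(sources)))]
            t = targets[int(red.integers(0, len(targets)))]
            if s == t or (s, t) in forbidden or (s, t) in out:
                continue
            out.add((s, t))
        return out

    tables: dict[str, InteractionTable] = {}
    tg_edges = planted_edges["TF-GENE"] | _decoys("TF-GENE", tfs, genes, planted_edges["TF-GENE"])
    mg_edges = planted_edges["MIR-GENE"] | _decoys("MIR-GENE", mirs, genes, planted_edges["MIR-GENE"])
    # decoy TF-MIR edges must not reverse a planted MIR-TF edge (and vice
    # versa): a stray mutual pair would silently re-type a planted simple
    # loop as composite
    forbid_tm = planted_edges["TF-MIR"] | {(t, m) for (m, t) in planted_edges["MIR-TF"]}
    tm_edges = planted_edges["TF-MIR"] | _decoys("TF-MIR", tfs, mirs, forbid_tm)
    forbid_mt = planted_edges["MIR-TF"] | {(m, t) for (t, m) in tm_edges}
    mt_edges = planted_edges["MIR-TF"] | _decoys("MIR-TF", mirs, tfs, forbid_mt)
    for cls, edges in (("TF-GENE", tg_edges), ("TF-MIR", tm_edges),
                       ("MIR-GENE", mg_edges), ("MIR-TF", mt_edges)):
        rows = sorted(edges)
        tables[cls] = InteractionTable(cls, pd.DataFrame(
            {"source": [s for s, _ in rows], "target": [t for _, t in rows],
             "evidence": ["planted" if (s, t) in planted_edges[cls] else "decoy"
                           for s, t in rows]},
        ))

    # ---------------- gene sets and hallmark categories
    rg = rngs["genesets"]
    sets: list[GeneSet] = []
    planted_pair_genes = hypo_genes + hyper_genes
    categories: dict[str, str] = {}
    from .enrichment import HALLMARK_CATEGORIES

    for i in range(cfg.n_gene_sets):
        sid = f"SET{i + 1:03d}"
        if i < 3 and len(planted_pair_genes) >= 10:
            picked = list(rg.choice(planted_pair_genes, size=min(30, len(planted_pair_genes)),
                                    replace=False))
            picked += list(rg.choice(genes, size=10, replace=False))
        else:
            picked = list(rg.choice(rna_features, size=int(rg.integers(20, 60)), replace=False))
        members = tuple(OrderedDict.fromkeys(picked))
        sets.append(GeneSet(sid, f"synthetic set {i + 1}", members))
        categories[sid] = HALLMARK_CATEGORIES[i % len(HALLMARK_CATEGORIES)]
    gene_sets = GeneSetCollection.from_sets(sets)

    truth = SyntheticTruth(
        probes={
            probes[i]: {
                "direction": "hypo" if probe_dir[i] < 0 else "hyper",
                "true_delta": float(probe_dir[i] * probe_delta[i]),
            }
            for i in range(cfg.n_probes)
            if probe_dir[i] != 0
        },
        pairs=pairs,
        motifs=planted_motifs,
        mrtfs=mrtf_truth,
        de_genes={f: cfg.planted_log2fc * d for f, d in de_dir.items()
                  if f in rna_index},
        de_mirnas={f: cfg.planted_log2fc * d for f, d in de_dir.items()
                   if f in mir_index},
        ffls=planted_ffls,
        universe={"probes": probes, "genes": genes, "tfs": tfs, "mirnas": mirs},
    )
    inputs = StudyInputs(
        beta=beta,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        sheet=sheet,
        probe_ann=probe_ann,
        gene_ann=gene_ann,
        motif_occurrences=motif_occurrences,
        motif_tf_map=motif_tf_map,
        interactions=tables,
        gene_sets=gene_sets,
        category_map=categories,
    )
    return inputs, truth


def write_study(inputs: StudyInputs, truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write the full input bundle plus truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(inputs.beta, outdir / "beta.tsv")
    write_matrix(inputs.gene_counts, outdir / "gene_counts.tsv")
    write_matrix(inputs.mirna_counts, outdir / "mirna_counts.tsv")
    write_sample_sheet(inputs.sheet, outdir / "samples.tsv")
    write_probe_annotation(inputs.probe_ann, outdir / "probes.tsv")
    write_gene_annotation(inputs.gene_ann, outdir / "genes.tsv")
    write_motif_occurrences(inputs.motif_occurrences, outdir / "motif_occurrences.tsv")
    write_motif_tf_map(inputs.motif_tf_map, outdir / "motif_tf_map.tsv")
    for cls, table in inputs.interactions.items():
        write_interactions(table, outdir / f"interactions_{cls.replace('-', '_').lower()}.tsv")
    write_gmt(inputs.gene_sets, outdir / "gene_sets.gmt")
    write_category_map(inputs.category_map, outdir / "hallmark_categories.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# recovery metrics


def _confusion(truth_set: set, found_set: set) -> dict:
    tp = len(truth_set & found_set)
    fp = len(found_set - truth_set)
    fn = len(truth_set - found_set)
    sens = tp / len(truth_set) if truth_set else float("nan")
    fdp = fp / len(found_set) if found_set else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "sensitivity": sens, "fdp": fdp}


def truth_recovery_report(truth: SyntheticTruth, results: Mapping[str, object]) -> dict:
    """Per-stage confusion counts of pipeline output vs the planted truth.

    ``results`` maps stage name to the found set: ``diffmeth`` (probe ids),
    ``pairs`` ((probe, gene) tuples), ``de_genes`` / ``de_mirnas`` (feature
    ids), ``mrtfs`` (TF ids), ``ffls`` ((type, tf, mirna, gene) tuples).
    Ids outside the simulated universe raise a hard error.
    """
    uni = truth.universe
    known_probes = set(uni["probes"])
    known_rna = set(uni["genes"]) | set(uni["tfs"])
    known_mirs = set(uni["mirnas"])
    report: dict[str, dict] = {}

    def _check(ids: set, known: set, stage: str) -> None:
        bad = ids - known
        if bad:
            raise ValueError(f"{stage}: ids not in the simulated universe: {sorted(bad)[:5]}")

    if "diffmeth" in results:
        found = set(results["diffmeth"])
        _check(found, known_probes, "diffmeth")
        report["diffmeth"] = _confusion(set(truth.probes), found)
    if "pairs" in results:
        found = {tuple(p) for p in results["pairs"]}
        _check({p for p, _ in found}, known_probes, "pairs")
        _check({g for _, g in found}, known_rna, "pairs")
        report["pairs"] = _confusion(set(truth.pairs), found)
    if "de_genes" in results:
        found = set(results["de_genes"])
        _check(found, known_rna, "de_genes")
        report["de_genes"] = _confusion(set(truth.de_genes), found)
    if "de_mirnas" in results:
        found = set(results["de_mirnas"])
        _check(found, known_mirs, "de_mirnas")
        report["de_mirnas"] = _confusion(set(truth.de_mirnas), found)
    if "mrtfs" in results:
        found = set(results["mrtfs"])
        _check(found, known_rna, "mrtfs")
        report["mrtfs"] = _confusion({m["tf"] for m in truth.mrtfs}, found)
    if "ffls" in results:
        found = {tuple(f) for f in results["ffls"]}
        for _, t, m, g in found:
            _check({t}, known_rna, "ffls")
            _check({m}, known_mirs, "ffls")
            _check({g}, known_rna, "ffls")
        report["ffls"] = _confusion({f.key() for f in truth.ffls}, found)
    return report
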