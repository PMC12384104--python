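# Methods

## Overview

`fflscope` implements an integrative epigenomic workflow for two-group
(tumor vs normal) studies that carry three assays on overlapping samples:
450K-style DNA methylation beta values, RNA-seq counts (genes and
transcription factors) and miRNA-seq counts. The workflow proceeds in five
stages:

1. **Differential expression** — simplified negative-binomial Wald test.
2. **Differential methylation** — distal probes with a large tumor−normal
   beta shift, paired to nearby anti-correlated genes, followed by motif
   odds-ratio enrichment and master-regulator TF (MRTF) nomination.
3. **Network assembly** — database-supplied candidate edges restricted to
   the differential node sets and signed by Pearson correlation.
4. **FFL discovery** — exact enumeration of three-node feed-forward loops
   (TF-mediated, miRNA-mediated, composite), coherence classification, and
   significance against degree-preserving random networks.
5. **Enrichment** — hypergeometric over-representation of the loop genes
   and of miRNA target unions against GMT collections, with BH FDR control
   and hallmark process-category rollups.

A synthetic-study generator with planted ground truth exercises the whole
chain; its planted effects are the package's validation currency.

## Differential methylation (supervised, distal probes)

Only probes flagged distal are tested; when the flag is absent it is
derived as "more than 2 kb from the nearest annotated TSS" (configurable).
Each direction (hypo-, hypermethylated in tumor) is tested separately with
a one-tailed Welch t-test on per-probe beta values; a probe is called when
raw p < 0.01 **and** |mean_tumor − mean_normal| ≥ 0.3. No multiple-testing
correction is applied beyond these raw thresholds — the pipeline
reproduces a raw-threshold protocol, and the effect-size floor of 0.3 is
the operative filter (the t-test p is almost always smaller at these
sample sizes). Probes with fewer than 2 non-missing values in either group
are skipped and counted in the log. Missing beta values (`NA`) are
excluded pairwise from all statistics; missing counts are rejected at load.

**Design choice: supervised mode.** The two sample groups are labeled, so
group means are compared directly; the unsupervised extreme-quintile
variant used by some enhancer-linking tools for heterogeneous cohorts is
not implemented.

## Probe–gene pairing

For each significant probe, candidate genes are the 10 nearest TSS on each
side (fewer near chromosome ends; ties broken by gene id). Samples are
split into the **M** group (upper 20% by that probe's beta, minimum 5) and
the **U** group (lower 20%); ties in beta are broken by sample order. The
pairing statistic is

    stat = mean log2 expr(M) − mean log2 expr(U),

with expression log2(normalized count + 1) using median-of-ratios size
factors. The null distribution is the same statistic computed for random
distal probes (each contributing its own M/U split) against the same gene;
the empirical raw p is the +1-corrected fraction of 10,000 draws at least
as extreme in the anti-correlated (negative) direction. A pair is retained
at raw p < 0.05.

Implementation note: per probe the M/U split is a fixed contrast vector,
so the statistic of every (probe, gene) combination and the full null set
of a gene over all distal probes are single matrix–vector products. Null
draws sample (with replacement) from the precomputed per-probe statistics;
the tested probe is not excluded from the null pool (its weight is
1/n_distal and excluding it changes nothing at realistic scale). The +1
correction keeps the p-values valid (never liberal); the unit test checks
the pooled null ECDF never rises above the diagonal materially.

**Known property, by design:** the null is "random distal probe", not
"random probe matched on group structure". Any gene whose expression
separates the groups will pair with any nearby differentially methylated
probe, whether or not the probe drives it. This mirrors the supervised
protocol being reproduced; on synthetic data it shows up as a high
false-discovery proportion at the pair stage while sensitivity for truly
linked pairs stays at 1.0.

## Motif enrichment and master regulators

Per motif, a 2×2 table of motif presence × paired-set membership is built
over the distal universe (background = distal probes not in the paired
set): OR = (a/b)/(c/d), with the Haldane–Anscombe 0.5 correction when any
cell is zero and a normal-approximation 95% CI on log OR. A motif is kept
when the CI lower bound exceeds 1.1 and at least 10 paired probes carry it.

For each enriched motif, the average beta over its paired probes defines
M/U extremes as above; every candidate TF mapped to the motif is tested by
a one-sided Mann–Whitney rank-sum of its log2 expression between M and U
(both directions; smaller p reported, p < 0.05). Direction `down` means
lower expression in the methylated extreme (the classical anti-correlated
master regulator); `up` is reported symmetrically.

## Differential expression

A deliberately simplified DESeq2-style engine: median-of-ratios size
factors (features positive in all samples; fallback to features positive
in ≥ 90% of samples), normalized group means, gene-wise method-of-moments
dispersion α pooled across groups from Var = μ + αμ² (floored at 1e−8),
log2fc = log2((μ_t + ε)/(μ_n + ε)) with ε = 0.5, a delta-method standard
error from the NB variance, and a two-sided normal Wald p. Features are
called up/down at |log2fc| > 0.58 with raw p < 0.05; BH q-values are
reported alongside for the record. No dispersion shrinkage, LFC moderation
or independent filtering — when a full DESeq2 run is available, its table
can be passed through verbatim (`--de-table` / `PipelineConfig.de_table`)
so downstream stages consume it unchanged. On simulated nulls the Wald
test's type-I error at p < 0.05 sits near 0.05 (the acceptance script
recomputes it), and label swap negates every log2fc exactly.

## Network assembly

Candidate edges come exclusively from the user-supplied interaction tables
(TF→gene, TF→miRNA, miRNA→gene, miRNA→TF); the pipeline never invents an
edge, and direction always comes from the table. Node sets: genes = genes
of retained pairs, stratified hypo/hyper by their probe (a gene reached by
both directions enters both strata, with a warning); TFs = differentially
expressed TFs plus DE master regulators; miRNAs = DE miRNAs. Within each
stratum, TF→gene and miRNA→gene edges to the stratum's genes are signed
first by Pearson correlation of log2 expression over shared samples (kept
at p < 0.05, sign = sign(r), no |r| floor); regulators retaining at least
one gene edge form the stratum's TF/miRNA sets, among which TF–miRNA edges
in both orientations are then signed. miRNA correlations use the
intersection of the RNA and miRNA assays' samples (the motivating cohorts
differ: 134/84 vs 129/56); edges with fewer than 10 shared samples are
dropped and counted. The stratum-membership rule for TF–miRNA edges is
this package's convention — without it both strata would carry identical
TF–miRNA edge sets.

## FFL discovery

Templates on the signed tripartite graph:

* TF-mediated: TF→miRNA, TF→gene, miRNA→gene
* miRNA-mediated: miRNA→TF, miRNA→gene, TF→gene
* composite: mutual TF↔miRNA plus both gene edges

Enumeration is exact (at three nodes on a typed graph this is a handful of
hash-map intersections; no sampling is needed). A triple with a mutual
TF↔miRNA pair is emitted once, as composite only — never additionally as
the two simple loops — so the three type counts partition the loop set.

**Coherence.** The master's direct sign onto the gene is compared with the
product of signs along master→intermediary→gene: equal → coherent,
opposite → incoherent. Of the 8 sign assignments of a simple loop exactly
4 are coherent. Composite loops are evaluated from both masters; when the
two mutual edges carry the same sign (always true for correlation-derived
signs, which assign both directed edges of a mutual pair the sign of the
same Pearson r) the two evaluations provably agree, and the loop is
labeled by that shared verdict. Disagreement — possible only for
hand-crafted inputs with unequal mutual signs — yields `unclassified`.

**Significance.** Null networks are built by repeated double-edge swaps
within each edge class (10 attempts per edge by default), which preserves
every node's in/out degree per class exactly; signs stay attached to the
source side of each edge. The observed count per loop type is compared
with 1,000 null networks: z = (observed − mean)/sd, and the empirical
p = (1 + #{null ≥ observed})/(1 + n_random) — the +1 avoids zero p.
Classes with fewer than 2 edges cannot be swapped and are left fixed (with
a warning); an ensemble in which no randomization can change the count
therefore reports z = 0 and p = 1.

## Enrichment

Upper-tail hypergeometric ORA with BH correction across all tested sets;
the universe is all features measured on the relevant assay (not the
genome). Sets are intersected with the universe first; empty intersections
are skipped. miRNA queries are mapped to the union (not multiset) of their
targets in the supplied table before testing. Significant sets (FDR <
0.05) roll up into the eight hallmark process categories (cellular
component, development, DNA damage, immune, metabolic, pathway,
proliferation, signaling); unmapped sets count as `pathway` with a
warning.

## Synthetic-study generator

The generator emulates the motivating study's shape at desk scale. Default
conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n_tumor / n_normal | 134 / 84 | methylation + RNA cohort |
| n_tumor_mirna / n_normal_mirna | 129 / 56 | miRNA cohort (subset) |
| n_probes / n_genes / n_tfs / n_mirnas | 2000 / 800 / 60 / 200 | feature counts |
| n_hypo_pairs / n_hyper_pairs | 99 / 53 | planted probe–gene pairs |
| delta_beta | 0.5 | planted beta shift (probability scale) |
| beta_logit_sd | 0.5 | per-sample logit-scale noise |
| planted_log2fc | 1.5 | planted DE effect (safely above the 0.58 call threshold) |
| nb_mean / nb_dispersion | 200 / 0.1 | NB count model (per-feature log-normal spread) |
| libsize_fold_range | 4 | log-uniform library-size range |
| n_ffls | 3+3 TF, 3+3 miRNA, 1+1 composite | planted loops per type × coherence |
| motif_odds / motif_bg_rate | 8 / 0.03 | planted motif enrichment |

Beta values are simulated on the logit scale (Gaussian noise, inverse
logit, clipped to [0.01, 0.99]) — this keeps values in range with the
heteroscedasticity real arrays show (variance shrinking toward 0 and 1).
The inverse-logit transform slightly compresses extreme group means, so a
configured shift of 0.5 realizes as ≈ 0.48 empirically; the recovery
checks measure the realized shift against the configured one within 0.05.

Each planted pair's gene receives log-expression −meth_slope·(β − β̄) from
its probe (slope 2.0), a monotone decreasing link that creates both the
between-group shift and within-group anti-correlation the pairing stage
looks for. Counts are NB with per-feature log-normal dispersion and
log-uniform library sizes over a 4-fold range (exercising the size-factor
estimator). miRNA repression is encoded purely as negative expression
correlation; no kinetic model is attempted.

**Planting loops.** The three members of a planted loop share
multivariate-normal biological noise whose pairwise correlations are
±0.45 with the planted edge signs (the sign pattern of a coherent loop
has product +1 and of an incoherent loop −1; both are positive-definite at
0.45). Group directions are chosen to reinforce the master path: the
intermediary's DE direction is the master's times the master→intermediary
sign, and the gene's methylation stratum follows the master→gene sign. In
an incoherent loop one gene edge is then necessarily opposed by the group
structure; loop members therefore get a larger biological noise sd (1.0
vs 0.35 background) and loop genes a slightly smaller methylation shift
(0.4 vs 0.5), so the planted correlation sign carries that edge. Loop
TFs/miRNAs/genes are distinct across loops, keeping each loop's covariance
a 3×3 block. Decoy edges are sampled per class avoiding planted edges and
— for the TF–miRNA classes — avoiding reversals that would silently
re-type a planted simple loop as composite.

**What the generator does not emulate:** 450K probe-density and
cross-reactivity structure, copy-number/purity confounding, batch effects,
promoter methylation, and any real miRNA target biology (targets are
arbitrary ids). Passing tests therefore demonstrate that the statistical
machinery recovers what it claims under its own model assumptions — not
that those assumptions hold in any given cohort.

Randomness: a single global seed spawns one named child stream per
component (layout, beta, expression, miRNA, library sizes, dispersions,
motifs, edges, gene sets), so identical (config, seed) reruns are
byte-identical and changing one component's parameters does not reshuffle
the others.

## Numerical and reporting choices

* Beta bounds are enforced with 1e−9 tolerance; identifiers are
  case-sensitive opaque strings, never normalized.
* All tie-breaks (M/U splits, candidate-gene ordering) are deterministic:
  stable sorts with sample/gene order as the secondary key.
* Degenerate inputs: constant expression vectors are skipped in pairing
  and correlation (a correlation is undefined); all-zero count features
  report `ns` with NaN statistics; motifs absent from the distal universe
  are skipped.
* `report.json` contains only deterministic content (counts, parameter
  echo, seed) and reproduces byte-for-byte under a fixed seed; stage
  timings and input checksums live in `manifest.json`.
* Problem sizes in the validation suite: null calibrations pool 25
  simulated studies per check (2,000 probes for methylation, 5,000
  features for the Wald test, 3,000 probe–gene tests, 10,000 candidate
  edges); recovery checks run 25 full default-condition pipelines. These
  sizes give Monte-Carlo standard errors comfortably below the tolerances
  being checked while keeping a full validation run in the low minutes on
  one core.

## Known limitations

* The Wald test uses a normal reference with method-of-moments dispersion;
  it is honest at n ≳ 30 per group but anticonservative for a handful of
  samples. Use an external DE table for small designs.
* Pair discovery inherits the supervised protocol's confounding (see
  above): it controls the probe-level null, not gene-level specificity.
* Composite-loop coherence for inputs with unequal mutual signs is a
  convention of this package (`unclassified`), not an established
  definition.
* Evidence tiers on interaction edges are carried through but not
  interpreted; filtering by evidence is left to input preparation.
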