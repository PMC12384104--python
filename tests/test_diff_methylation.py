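import numpy as np
import pandas as pd
import pytest

from fflscope.diff_methylation import (
    DiffMethResult,
    PairEngine,
    candidate_genes,
    derive_distal_flags,
    enrich_motifs,
    find_diff_meth_probes,
    mu_groups,
    nominate_master_regulators,
    pair_probe_gene,
)
from fflscope.io_formats import (
    BetaMatrix,
    GeneAnnotation,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)


def _sheet(nt, nn):
    return SampleSheet(pd.DataFrame({
        "sample": [f"T{i}" for i in range(nt)] + [f"N{i}" for i in range(nn)],
        "group": ["tumor"] * nt + ["normal"] * nn,
    }))


def _ann(probes, distal=True):
    return ProbeAnnotation(pd.DataFrame({
        "probe": probes,
        "chrom": "chr1",
        "position": np.arange(len(probes)) * 10000,
        "is_distal": distal,
    }))


class TestDiffMeth:
    def test_forced_separation_is_hyper(self):
        rng = np.random.default_rng(0)
        nt, nn = 10, 10
        vals = np.hstack([
            np.clip(0.9 + rng.normal(0, 0.01, (5, nt)), 0, 1),
            np.clip(0.2 + rng.normal(0, 0.01, (5, nn)), 0, 1),
        ])
        beta = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)],
                                       columns=_sheet(nt, nn).frame["sample"]))
        res = find_diff_meth_probes(beta, _sheet(nt, nn), _ann(beta.probe_ids), direction="hyper")
        assert len(res) == 5
        assert all(r.direction == "hyper" for r in res)
        assert all(abs(r.delta - 0.7) < 0.05 for r in res)
        assert find_diff_meth_probes(beta, _sheet(nt, nn), _ann(beta.probe_ids),
                                     direction="hypo") == []

    def test_small_delta_excluded_despite_tiny_p(self):
        rng = np.random.default_rng(1)
        nt = nn = 50
        vals = np.hstack([
            np.clip(0.50 + rng.normal(0, 0.005, (3, nt)), 0, 1),
            np.clip(0.45 + rng.normal(0, 0.005, (3, nn)), 0, 1),
        ])
        beta = BetaMatrix(pd.DataFrame(vals, index=["a", "b", "c"],
                                       columns=_sheet(nt, nn).frame["sample"]))
        assert find_diff_meth_probes(beta, _sheet(nt, nn), _ann(beta.probe_ids),
                                     direction="hyper") == []

    def test_only_distal_probes_tested(self):
        rng = np.random.default_rng(2)
        vals = np.hstack([np.full((2, 5), 0.9), np.full((2, 5), 0.1)])
        vals = np.clip(vals + rng.normal(0, 0.01, vals.shape), 0, 1)
        beta = BetaMatrix(pd.DataFrame(vals, index=["d1", "p1"],
                                       columns=_sheet(5, 5).frame["sample"]))
        ann = ProbeAnnotation(pd.DataFrame({
            "probe": ["d1", "p1"], "chrom": "chr1", "position": [0, 100],
            "is_distal": [True, False],
        }))
        res = find_diff_meth_probes(beta, _sheet(5, 5), ann, direction="hyper")
        assert [r.probe_id for r in res] == ["d1"]

    def test_stricter_thresholds_shrink_the_result_set(self):
        rng = np.random.default_rng(3)
        nt = nn = 30
        vals = np.clip(rng.uniform(0.1, 0.9, (200, 1))
                       + np.hstack([rng.normal(0.25, 0.15, (200, nt)),
                                    rng.normal(0, 0.15, (200, nn))]), 0, 1)
        beta = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(200)],
                                       columns=_sheet(nt, nn).frame["sample"]))
        loose = {r.probe_id for r in find_diff_meth_probes(
            beta, _sheet(nt, nn), _ann(beta.probe_ids), sig_diff=0.2, p_cut=0.05, direction="hyper")}
        tight_effect = {r.probe_id for r in find_diff_meth_probes(
            beta, _sheet(nt, nn), _ann(beta.probe_ids), sig_diff=0.3, p_cut=0.05, direction="hyper")}
        tight_p = {r.probe_id for r in find_diff_meth_probes(
            beta, _sheet(nt, nn), _ann(beta.probe_ids), sig_diff=0.2, p_cut=0.001, direction="hyper")}
        assert tight_effect <= loose
        assert tight_p <= loose

    def test_hypo_and_hyper_sets_disjoint(self):
        rng = np.random.default_rng(4)
        nt = nn = 20
        shift = rng.choice([-0.4, 0.4], size=(100, 1))
        vals = np.clip(0.5 + np.hstack([shift + rng.normal(0, 0.05, (100, nt)),
                                        rng.normal(0, 0.05, (100, nn))]), 0, 1)
        beta = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(100)],
                                       columns=_sheet(nt, nn).frame["sample"]))
        hypo = {r.probe_id for r in find_diff_meth_probes(
            beta, _sheet(nt, nn), _ann(beta.probe_ids), direction="hypo")}
        hyper = {r.probe_id for r in find_diff_meth_probes(
            beta, _sheet(nt, nn), _ann(beta.probe_ids), direction="hyper")}
        assert hypo and hyper
        assert not hypo & hyper

    def test_probes_with_missing_groups_skipped(self):
        vals = np.array([[0.9, np.nan, 0.1, 0.1], [0.9, 0.9, 0.1, 0.1]])
        beta = BetaMatrix(pd.DataFrame(vals, index=["cgA", "cgB"],
                                       columns=_sheet(2, 2).frame["sample"]))
        res = find_diff_meth_probes(beta, _sheet(2, 2), _ann(beta.probe_ids),
                                    p_cut=0.5, direction="hyper")
        assert [r.probe_id for r in res] == ["cgB"]


class TestCandidateGenes:
    def _genes(self, positions, chrom="chr1"):
        return GeneAnnotation(pd.DataFrame({
            "gene": [f"G{p}" for p in positions], "chrom": chrom,
            "tss": positions, "strand": "+",
        }))

    def test_nearest_on_each_side(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "probe": ["p"], "chrom": "chr1", "position": [1000], "is_distal": True}))
        out = candidate_genes("p", ann, self._genes([900, 1100, 5000]), k_each_side=1)
        assert set(out) == {"G900", "G1100"}

    def test_probe_left_of_all_genes(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "probe": ["p"], "chrom": "chr1", "position": [10], "is_distal": True}))
        out = candidate_genes("p", ann, self._genes([500, 900, 5000]), k_each_side=2)
        assert out == ["G500", "G900"]

    def test_no_same_chromosome_gene_gives_empty(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "probe": ["p"], "chrom": "chr9", "position": [10], "is_distal": True}))
        assert candidate_genes("p", ann, self._genes([500])) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(rng.choice(100000, size=40, replace=False))
        genes = self._genes(positions)
        pos = int(rng.integers(0, 100000))
        ann = ProbeAnnotation(pd.DataFrame({
            "probe": ["p"], "chrom": "chr1", "position": [pos], "is_distal": True}))
        k = int(rng.integers(1, 6))
        got = set(candidate_genes("p", ann, genes, k_each_side=k))
        left = sorted((g for g in positions if g < pos), key=lambda g: pos - g)[:k]
        right = sorted((g for g in positions if g >= pos), key=lambda g: g - pos)[:k]
        assert got == {f"G{g}" for g in left + right}


def test_derive_distal_flags_uses_tss_distance():
    probes = ProbeAnnotation(pd.DataFrame({
        "probe": ["near", "far"], "chrom": "chr1", "position": [1000, 50000],
        "is_distal": [pd.NA, pd.NA],
    }))
    genes = GeneAnnotation(pd.DataFrame({
        "gene": ["G"], "chrom": ["chr1"], "tss": [500], "strand": ["+"]}))
    out = derive_distal_flags(probes, genes)
    assert list(out.frame["is_distal"]) == [False, True]


class TestMUGroups:
    def test_extremes_and_tie_break_by_order(self):
        s = pd.Series([0.5] * 10, index=[f"S{i}" for i in range(10)])
        m, u = mu_groups(s, frac=0.2, min_per_side=2)
        assert u == ["S0", "S1"]
        assert m == ["S8", "S9"]

    def test_too_few_samples_raises(self):
        s = pd.Series(np.linspace(0, 1, 8), index=[f"S{i}" for i in range(8)])
        with pytest.raises(ValidationError):
            mu_groups(s, frac=0.2, min_per_side=5)


class TestPairing:
    def _fixture(self, seed=0, n=60, n_probes=50):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        beta = BetaMatrix(pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(n_probes, n)),
            index=[f"cg{i}" for i in range(n_probes)], columns=samples))
        return beta, samples, rng

    def test_perfect_anticorrelation_retained(self):
        beta, samples, rng = self._fixture()
        expr = pd.DataFrame(
            {"G1": 10 - 8 * beta.data.loc["cg0"] + rng.normal(0, 0.01, len(samples))},
        ).T
        expr.columns = samples
        engine = PairEngine(beta, expr, beta.probe_ids)
        dm = DiffMethResult("cg0", 0.8, 0.2, 0.6, 1e-5, "hyper")
        pair = pair_probe_gene(dm, "G1", engine, distance=1000, n_perm=2000,
                               rng=np.random.default_rng(1))
        assert pair is not None
        assert pair.statistic < 0
        assert pair.raw_p < 0.05

    def test_fixed_seed_reproduces_raw_p(self):
        beta, samples, rng = self._fixture(seed=2)
        expr = pd.DataFrame([rng.normal(5, 1, len(samples))], index=["G1"], columns=samples)
        engine = PairEngine(beta, expr, beta.probe_ids)
        dm = DiffMethResult("cg3", 0.7, 0.3, 0.4, 1e-4, "hyper")
        ps = []
        for _ in range(2):
            pair = pair_probe_gene(dm, "G1", engine, distance=0, n_perm=10,
                                   raw_p_cut=1.01, rng=np.random.default_rng(7))
            ps.append(pair.raw_p)
        assert ps[0] == ps[1]

    def test_constant_expression_skipped(self):
        beta, samples, _ = self._fixture(seed=3)
        expr = pd.DataFrame([np.full(len(samples), 3.0)], index=["G1"], columns=samples)
        engine = PairEngine(beta, expr, beta.probe_ids)
        dm = DiffMethResult("cg0", 0.7, 0.3, 0.4, 1e-4, "hyper")
        assert pair_probe_gene(dm, "G1", engine, distance=0, n_perm=10,
                               rng=np.random.default_rng(0)) is None

    def test_null_permutation_p_values_stochastically_valid(self):
        """Under independence the empirical pair p-values must be (at least)
        uniform: their ECDF never exceeds the diagonal materially."""
        beta, samples, rng = self._fixture(seed=4, n=80, n_probes=120)
        expr = pd.DataFrame(rng.normal(5, 1, size=(40, len(samples))),
                            index=[f"G{i}" for i in range(40)], columns=samples)
        engine = PairEngine(beta, expr, beta.probe_ids)
        prng = np.random.default_rng(11)
        pvals = []
        for gi in range(40):
            nulls = engine.null_statistics(f"G{gi}")
            for probe in beta.probe_ids[:15]:
                obs = engine.statistic(probe, f"G{gi}")
                draws = nulls[prng.integers(0, len(nulls), size=500)]
                pvals.append((1 + np.sum(draws <= obs)) / 501)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        assert np.max(ecdf - pvals) < 0.08  # conservative or uniform, never liberal


class TestMotifEnrichment:
    def test_two_by_two_example_matches_brute_force_table(self):
        """20 paired probes (10 with the motif) against 90 background-only
        probes (10 with the motif): brute-force margins give a=10, b=10,
        c=10, d=80, hence OR = (10/10)/(10/80) = 8.0."""
        paired = [f"p{i}" for i in range(20)]
        background = [f"b{i}" for i in range(90)]
        occurrences = pd.DataFrame(
            {"motif": "M1", "probe": paired[:10] + background[:10]})
        # independent brute-force construction of the 2x2 table
        with_motif = set(occurrences["probe"])
        a = sum(1 for p in paired if p in with_motif)
        b = sum(1 for p in paired if p not in with_motif)
        c = sum(1 for p in background if p in with_motif)
        d = sum(1 for p in background if p not in with_motif)
        assert (a, b, c, d) == (10, 10, 10, 80)
        expected_or = (a / b) / (c / d)
        assert expected_or == 8.0
        out = enrich_motifs(paired, paired + background, occurrences,
                            lower_or=1.1, min_incidence=10)
        assert len(out) == 1
        assert out[0].odds_ratio == pytest.approx(expected_or)
        assert out[0].table == (10, 10, 10, 80)
        assert out[0].ci_lower > 1.1

    def test_min_incidence_rejects_despite_huge_or(self):
        paired = [f"p{i}" for i in range(30)]
        background = [f"b{i}" for i in range(300)]
        occurrences = pd.DataFrame({"motif": "M1", "probe": paired[:9]})
        assert enrich_motifs(paired, paired + background, occurrences,
                             min_incidence=10) == []
        kept = enrich_motifs(paired, paired + background, occurrences, min_incidence=9)
        assert len(kept) == 1

    def test_zero_cell_gets_haldane_correction(self):
        paired = [f"p{i}" for i in range(30)]
        background = [f"b{i}" for i in range(100)]
        occurrences = pd.DataFrame({"motif": "M1", "probe": paired[:20]})
        out = enrich_motifs(paired, paired + background, occurrences, min_incidence=10)
        assert len(out) == 1
        assert np.isfinite(out[0].odds_ratio)
        a, b, c, d = 20.5, 10.5, 0.5, 100.5
        assert out[0].odds_ratio == pytest.approx((a / b) / (c / d))

    def test_random_paired_set_yields_no_enrichment(self):
        rng = np.random.default_rng(5)
        probes = [f"cg{i}" for i in range(500)]
        rows = [("M" + str(m), p) for m in range(5) for p in probes if rng.random() < 0.1]
        occurrences = pd.DataFrame(rows, columns=["motif", "probe"])
        hits = 0
        for seed in range(10):
            paired = list(np.random.default_rng(seed).choice(probes, size=60, replace=False))
            hits += len(enrich_motifs(paired, probes, occurrences))
        # 5 motifs x 10 seeds: the CI-lower filter admits only rare flukes
        assert hits / 50 <= 0.1

    def test_paired_must_be_subset_of_distal(self):
        with pytest.raises(ValidationError):
            enrich_motifs(["a"], ["b"], pd.DataFrame({"motif": ["M"], "probe": ["b"]}))


class TestMasterRegulators:
    def _setup(self, tf_effect):
        rng = np.random.default_rng(0)
        n = 60
        samples = [f"S{i}" for i in range(n)]
        beta_row = np.linspace(0.1, 0.9, n)
        beta = BetaMatrix(pd.DataFrame([beta_row, beta_row],
                                       index=["cg1", "cg2"], columns=samples))
        expr = pd.DataFrame(
            [tf_effect * beta_row + rng.normal(0, 0.05, n)], index=["TF1"], columns=samples)
        from fflscope.diff_methylation import EnrichedMotif

        enriched = [EnrichedMotif("M1", 5.0, 2.0, 12, (12, 8, 5, 95))]
        tf_map = pd.DataFrame({"motif": ["M1"], "tf": ["TF1"]})
        return enriched, tf_map, {"M1": ["cg1", "cg2"]}, beta, expr

    def test_anticorrelated_tf_reported_down(self):
        enriched, tf_map, paired, beta, expr = self._setup(tf_effect=-5.0)
        out = nominate_master_regulators(enriched, tf_map, paired, beta, expr)
        assert len(out) == 1
        assert out[0].tf_id == "TF1"
        assert out[0].direction == "down"

    def test_flat_tf_not_reported(self):
        enriched, tf_map, paired, beta, expr = self._setup(tf_effect=0.0)
        expr.loc["TF1"] = 3.0
        assert nominate_master_regulators(enriched, tf_map, paired, beta, expr) == []

    def test_missing_tf_skipped(self):
        enriched, tf_map, paired, beta, expr = self._setup(tf_effect=-5.0)
        tf_map = pd.DataFrame({"motif": ["M1"], "tf": ["ABSENT"]})
        assert nominate_master_regulators(enriched, tf_map, paired, beta, expr) == []
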