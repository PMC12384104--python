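import numpy as np
import pandas as pd
import pytest

from fflscope.diff_methylation import MasterRegulator, ProbeGenePair
from fflscope.io_formats import InteractionTable
from fflscope.network_assembly import (
    assemble_nodes,
    build_network,
    sign_edges,
    summarize_network,
)


def _de(features, statuses):
    return pd.DataFrame({"status": statuses}, index=pd.Index(features, name="feature"))


def _table(cls, edges):
    return InteractionTable(cls, pd.DataFrame(
        {"source": [s for s, _ in edges], "target": [t for _, t in edges], "evidence": ""}))


def _expr(rows, samples, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(rng.normal(5, 1, size=(len(rows), len(samples))),
                        index=rows, columns=samples)


class TestAssembleNodes:
    def test_minimal_assembly(self):
        pairs = [ProbeGenePair("p1", "G1", -1.0, 0.01, 5000, "hyper")]
        nodes = assemble_nodes(pairs, _de(["T1"], ["up"]), _de(["m1"], ["down"]),
                               [], tf_ids={"T1"})
        assert nodes.genes == {"hypo": set(), "hyper": {"G1"}}
        assert nodes.tfs == {"T1"}
        assert nodes.mirnas == {"m1"}

    def test_gene_with_probes_in_both_strata_lands_in_both(self):
        pairs = [ProbeGenePair("p1", "G1", -1.0, 0.01, 5000, "hyper"),
                 ProbeGenePair("p2", "G1", -1.0, 0.01, 8000, "hypo")]
        nodes = assemble_nodes(pairs, _de(["T1"], ["ns"]), _de(["m1"], ["up"]), [], {"T1"})
        assert nodes.genes["hypo"] == {"G1"}
        assert nodes.genes["hyper"] == {"G1"}

    def test_mrtf_joins_tf_set_only_if_de(self):
        pairs = [ProbeGenePair("p1", "G1", -1.0, 0.01, 5000, "hypo")]
        mrtfs = [MasterRegulator("T2", "M1", 0.001, "down"),
                 MasterRegulator("T3", "M1", 0.001, "down")]
        de = _de(["T1", "T2", "T3"], ["up", "down", "ns"])
        nodes = assemble_nodes(pairs, de, _de(["m1"], ["up"]), mrtfs, {"T1"})
        assert nodes.tfs == {"T1", "T2"}


class TestSignEdges:
    def test_linear_relation_gives_activation(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(30)]
        x = rng.normal(0, 1, 30)
        expr = pd.DataFrame([x, 2 * x + rng.normal(0, 0.01, 30)],
                            index=["T1", "G1"], columns=samples)
        out = sign_edges(_table("TF-GENE", [("T1", "G1")]), expr, expr, {"T1"}, {"G1"})
        assert len(out) == 1
        assert out.iloc[0]["sign"] == 1
        assert out.iloc[0]["r"] > 0.99

    def test_exact_negation_gives_repression(self):
        samples = [f"S{i}" for i in range(12)]
        x = np.linspace(0, 1, 12)
        expr = pd.DataFrame([x, -x], index=["m1", "G1"], columns=samples)
        out = sign_edges(_table("MIR-GENE", [("m1", "G1")]), expr, expr, {"m1"}, {"G1"})
        assert out.iloc[0]["sign"] == -1
        assert out.iloc[0]["r"] == pytest.approx(-1.0)
        assert out.iloc[0]["p"] < 1e-10

    def test_no_invented_edges(self):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(40)]
        tfs = [f"T{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(10)]
        expr = _expr(tfs + genes, samples, rng)
        edges = [(t, g) for t in tfs for g in genes if rng.random() < 0.3]
        table = _table("TF-GENE", edges)
        out = sign_edges(table, expr, expr, set(tfs), set(genes), r_p_cut=0.5)
        assert set(zip(out["source"], out["target"])) <= set(edges)

    def test_negating_one_vector_flips_exactly_its_edges(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(50)]
        expr = _expr(["T1", "T2", "G1", "G2"], samples, rng)
        table = _table("TF-GENE", [("T1", "G1"), ("T1", "G2"), ("T2", "G1")])
        base = sign_edges(table, expr, expr, {"T1", "T2"}, {"G1", "G2"}, r_p_cut=1.0)
        flipped_expr = expr.copy()
        flipped_expr.loc["G1"] = -flipped_expr.loc["G1"]
        flipped = sign_edges(table, flipped_expr, flipped_expr, {"T1", "T2"},
                             {"G1", "G2"}, r_p_cut=1.0)
        merged = base.merge(flipped, on=["source", "target"], suffixes=("_a", "_b"))
        touches = merged["target"] == "G1"
        assert (merged.loc[touches, "sign_a"] == -merged.loc[touches, "sign_b"]).all()
        assert (merged.loc[~touches, "sign_a"] == merged.loc[~touches, "sign_b"]).all()

    def test_permuted_expression_retention_near_p_cut(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(60)]
        tfs = [f"T{i}" for i in range(20)]
        genes = [f"G{i}" for i in range(50)]
        edges = [(t, g) for t in tfs for g in genes]
        kept = 0
        for seed in range(5):
            expr = _expr(tfs + genes, samples, np.random.default_rng(seed))
            out = sign_edges(_table("TF-GENE", edges), expr, expr, set(tfs),
                             set(genes), r_p_cut=0.05)
            kept += len(out)
        assert kept / (5 * len(edges)) == pytest.approx(0.05, abs=0.02)

    def test_insufficient_shared_samples_drops_edges(self):
        sa = [f"A{i}" for i in range(12)]
        sb = [f"B{i}" for i in range(12)]
        src = _expr(["T1"], sa)
        tgt = _expr(["G1"], sb)
        out = sign_edges(_table("TF-GENE", [("T1", "G1")]), src, tgt, {"T1"}, {"G1"})
        assert len(out) == 0


class TestBuildAndSummarize:
    def test_summary_matches_brute_force_groupby(self):
        rng = np.random.default_rng(5)
        rows = []
        for stratum in ("hypo", "hyper"):
            for cls, (sp, tp) in {"TF-GENE": ("T", "G"), "TF-MIR": ("T", "m"),
                                  "MIR-GENE": ("m", "G"), "MIR-TF": ("m", "T")}.items():
                for _ in range(int(rng.integers(0, 8))):
                    rows.append((stratum, cls, f"{sp}{rng.integers(0, 5)}",
                                 f"{tp}{rng.integers(0, 5)}", 0.5, 0.01, 1))
        edges = pd.DataFrame(rows, columns=["stratum", "edge_class", "source",
                                            "target", "r", "p", "sign"]).drop_duplicates(
            subset=["stratum", "edge_class", "source", "target"])
        summary = summarize_network(edges)
        for row in summary.itertuples(index=False):
            sub = edges[(edges["stratum"] == row.stratum)
                        & (edges["edge_class"] == row.edge_class)]
            assert row.n_interactions == len(sub)

    def test_empty_edge_list_all_zero(self):
        summary = summarize_network(pd.DataFrame(
            columns=["stratum", "edge_class", "source", "target", "r", "p", "sign"]))
        assert (summary["n_interactions"] == 0).all()
        assert len(summary) == 8  # 2 strata x 4 classes

    def test_build_network_restricts_to_stratum_members(self):
        rng = np.random.default_rng(6)
        samples = [f"S{i}" for i in range(40)]
        x = rng.normal(0, 1, 40)
        expr_g = pd.DataFrame(
            [x, x + rng.normal(0, 0.1, 40), rng.normal(0, 1, 40)],
            index=["T1", "G1", "G2"], columns=samples)
        expr_m = pd.DataFrame([-x + rng.normal(0, 0.1, 40)], index=["m1"], columns=samples)
        tables = {
            "TF-GENE": _table("TF-GENE", [("T1", "G1"), ("T1", "G2")]),
            "TF-MIR": _table("TF-MIR", [("T1", "m1")]),
            "MIR-GENE": _table("MIR-GENE", [("m1", "G1")]),
            "MIR-TF": _table("MIR-TF", [("m1", "T1")]),
        }
        from fflscope.network_assembly import NodeSets

        nodes = NodeSets(genes={"hypo": {"G1"}, "hyper": set()}, tfs={"T1"}, mirnas={"m1"})
        edges = build_network(tables, nodes, expr_g, expr_m)
        assert set(edges["stratum"]) == {"hypo"}
        assert ("G2" not in set(edges["target"]))
        tg = edges[edges["edge_class"] == "TF-GENE"]
        assert tg.iloc[0]["sign"] == 1
        mg = edges[edges["edge_class"] == "MIR-GENE"]
        assert mg.iloc[0]["sign"] == -1
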