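"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own enumeration code paths: the FFL
oracle iterates every ordered (TF, miRNA, gene) triple against the loop
templates directly on the edge set.
"""

import itertools

import pandas as pd

from fflscope.ffl_discovery import COMPOSITE, MIR_MEDIATED, TF_MEDIATED

EDGE_COLS = ["edge_class", "source", "target", "sign"]


def edges_frame(rows):
    return pd.DataFrame(rows, columns=EDGE_COLS)


def random_tripartite(rng, n_tf=6, n_mir=6, n_gene=8, p=0.25):
    rows = []
    tfs = [f"T{i}" for i in range(n_tf)]
    mirs = [f"m{i}" for i in range(n_mir)]
    genes = [f"G{i}" for i in range(n_gene)]
    for cls, sources, targets in (("TF-GENE", tfs, genes), ("TF-MIR", tfs, mirs),
                                  ("MIR-GENE", mirs, genes), ("MIR-TF", mirs, tfs)):
        for s in sources:
            for t in targets:
                if rng.random() < p:
                    rows.append((cls, s, t, int(rng.choice([-1, 1]))))
    return edges_frame(rows)


def brute_force_ffls(edges):
    """All ordered (TF, miRNA, gene) triples x templates, with composite
    precedence for mutual TF<->miRNA pairs."""
    sign = {(c, s, t): g for c, s, t, g in edges.itertuples(index=False)}
    tfs = sorted({r.source for r in edges.itertuples() if r.edge_class.startswith("TF")}
                 | {r.target for r in edges.itertuples() if r.edge_class == "MIR-TF"})
    mirs = sorted({r.source for r in edges.itertuples() if r.edge_class.startswith("MIR")}
                  | {r.target for r in edges.itertuples() if r.edge_class == "TF-MIR"})
    genes = sorted({r.target for r in edges.itertuples()
                    if r.edge_class in ("TF-GENE", "MIR-GENE")})
    out = set()
    for t, m, g in itertools.product(tfs, mirs, genes):
        tg = ("TF-GENE", t, g) in sign
        mg = ("MIR-GENE", m, g) in sign
        tm = ("TF-MIR", t, m) in sign
        mt = ("MIR-TF", m, t) in sign
        if not (tg and mg):
            continue
        if tm and mt:
            out.add((COMPOSITE, t, m, g))
        elif tm:
            out.add((TF_MEDIATED, t, m, g))
        elif mt:
            out.add((MIR_MEDIATED, t, m, g))
    return out
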