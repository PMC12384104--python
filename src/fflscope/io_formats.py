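"""Readers and writers for every table the pipeline touches.

All tabular I/O is TSV with a header row. Identifiers are case-sensitive
opaque strings; no symbol normalization is attempted. Beta matrices may
contain missing values (encoded ``NA``); count matrices may not. Readers
validate on load so downstream modules only ever see well-formed in-memory
objects, and they never silently drop rows: anything rejected is counted and
logged at WARNING level.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four regulatory edge classes of the tripartite network
EDGE_CLASSES = ("TF-GENE", "TF-MIR", "MIR-GENE", "MIR-TF")

#: node kind on either side of each edge class (sources of TF-* edges are
#: measured on the RNA assay; MIR-* sources on the miRNA assay)
EDGE_ENDPOINT_KINDS = {
    "TF-GENE": ("tf", "gene"),
    "TF-MIR": ("tf", "mirna"),
    "MIR-GENE": ("mirna", "gene"),
    "MIR-TF": ("mirna", "tf"),
}

BETA_TOL = 1e-9


class FormatError(ValueError):
    """The file cannot be parsed as the expected table layout."""


class ValidationError(ValueError):
    """The file parsed but its content violates an invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


# ---------------------------------------------------------------------------
# matrices


@dataclasses.dataclass
class BetaMatrix:
    """Probe x sample methylation fractions in [0, 1]; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < -BETA_TOL) | (vals > 1.0 + BETA_TOL)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1]: probe {self.data.index[i]!r} "
                f"sample {self.data.columns[j]!r} value {vals[i, j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclasses.dataclass
class CountMatrix:
    """Feature x sample raw counts (non-negative integers, no missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("count matrix contains missing values")
        if (vals.astype(float) < 0).any():
            raise ValidationError("count matrix contains negative values")
        if not np.allclose(vals.astype(float), np.round(vals.astype(float))):
            raise ValidationError("count matrix contains non-integer values")
        self.data = self.data.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def read_matrix(path: str | Path, kind: str) -> BetaMatrix | CountMatrix:
    """Read a feature x sample TSV matrix.

    ``kind`` is ``"beta"`` (values in [0,1], ``NA`` allowed) or ``"counts"``
    (non-negative integers, no missing).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if kind == "beta":
        return BetaMatrix(df.astype(float))
    if kind == "counts":
        if df.isna().any().any():
            raise ValidationError(f"{path}: missing values not allowed in counts")
        return CountMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(mat: BetaMatrix | CountMatrix, path: str | Path) -> None:
    df = mat.data
    if isinstance(mat, BetaMatrix):
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    else:
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample sheet and annotations


@dataclasses.dataclass
class SampleSheet:
    """Sample -> group ({tumor, normal}) assignment."""

    frame: pd.DataFrame  # columns: sample, group

    def __post_init__(self) -> None:
        _check_unique(self.frame["sample"], "sample ids")
        groups = set(self.frame["group"])
        if not groups <= {"tumor", "normal"}:
            raise ValidationError(f"unknown group labels: {sorted(groups - {'tumor', 'normal'})}")
        for g in ("tumor", "normal"):
            if g not in groups:
                raise ValidationError(f"group {g!r} is empty")

    def samples(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path, ["sample", "group"])
    return SampleSheet(df[["sample", "group"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class ProbeAnnotation:
    """Probe coordinates (0-based) and the distal flag.

    ``is_distal`` may be absent (all-NA); it can then be derived from a
    :class:`GeneAnnotation` via :func:`fflscope.diff_methylation.derive_distal_flags`.
    """

    frame: pd.DataFrame  # columns: probe, chrom, position, is_distal

    def __post_init__(self) -> None:
        _check_unique(self.frame["probe"], "probe ids")
        if (self.frame["position"] < 0).any():
            raise ValidationError("negative probe position")
        self.frame = self.frame.reset_index(drop=True)

    def distal_probes(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["is_distal"].fillna(False).astype(bool), "probe"])


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = _read_tsv(path, ["probe", "chrom", "position"])
    df["position"] = df["position"].astype(int)
    if "is_distal" in df.columns:
        df["is_distal"] = df["is_distal"].map(_parse_bool)
    else:
        df["is_distal"] = pd.NA
    return ProbeAnnotation(df[["probe", "chrom", "position", "is_distal"]])


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.frame.copy()
    out["is_distal"] = out["is_distal"].map(lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class GeneAnnotation:
    frame: pd.DataFrame  # columns: gene, chrom, tss, strand

    def __post_init__(self) -> None:
        _check_unique(self.frame["gene"], "gene ids")
        if not set(self.frame["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be + or -")
        self.frame = self.frame.reset_index(drop=True)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_tsv(path, ["gene", "chrom", "tss", "strand"])
    df["tss"] = df["tss"].astype(int)
    return GeneAnnotation(df[["gene", "chrom", "tss", "strand"]])


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction tables


@dataclasses.dataclass
class InteractionTable:
    """Directed regulatory edges of one class, de-duplicated.

    ``n_rejected`` counts input rows dropped (self-edges); together with
    ``n_duplicates`` it accounts for every input row.
    """

    edge_class: str
    frame: pd.DataFrame  # columns: source, target, evidence
    n_rejected: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise ValidationError(f"unknown edge class {self.edge_class!r}")
        self.frame = self.frame.reset_index(drop=True)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["source"], self.frame["target"]))


def read_interactions(path: str | Path, edge_class: str) -> InteractionTable:
    df = _read_tsv(path, ["source", "target"], allow_empty=True)
    if "evidence" not in df.columns:
        df["evidence"] = ""
    df = df[["source", "target", "evidence"]]
    n_in = len(df)
    self_mask = df["source"] == df["target"]
    n_self = int(self_mask.sum())
    if n_self:
        logger.warning("%s: dropped %d self-edge rows", path, n_self)
    df = df[~self_mask]
    n_before = len(df)
    df = df.drop_duplicates(subset=["source", "target", "evidence"])
    n_dup = n_before - len(df)
    assert n_in == len(df) + n_self + n_dup
    return InteractionTable(edge_class, df, n_rejected=n_self, n_duplicates=n_dup)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and small mapping tables


@dataclasses.dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]  # de-duplicated, first occurrence order


@dataclasses.dataclass
class GeneSetCollection:
    sets: "OrderedDict[str, GeneSet]"

    def __post_init__(self) -> None:
        for s in self.sets.values():
            if not s.members:
                raise ValidationError(f"gene set {s.set_id!r} has no members")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: OrderedDict[str, GeneSet] = OrderedDict()
        for s in sets:
            if s.set_id in out:
                raise ValidationError(f"duplicate set id {s.set_id!r}")
            out[s.set_id] = s
        return cls(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set id, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            members = tuple(OrderedDict.fromkeys(f for f in fields[2:] if f))
            sets.append(GeneSet(fields[0], fields[1], members))
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


def read_motif_occurrences(path: str | Path) -> pd.DataFrame:
    """Motif occurrence table: one (motif, probe) row per occurrence."""
    return _read_tsv(path, ["motif", "probe"], allow_empty=True).drop_duplicates()


def write_motif_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df[["motif", "probe"]].to_csv(path, sep="\t", index=False)


def read_motif_tf_map(path: str | Path) -> pd.DataFrame:
    """Motif -> candidate-TF family membership table."""
    return _read_tsv(path, ["motif", "tf"], allow_empty=True).drop_duplicates()


def write_motif_tf_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["motif", "tf"]].to_csv(path, sep="\t", index=False)


def read_category_map(path: str | Path) -> Mapping[str, str]:
    """Hallmark set-id -> process-category map."""
    df = _read_tsv(path, ["set_id", "category"])
    return dict(zip(df["set_id"], df["category"]))


def write_category_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"set_id": list(mapping.keys()), "category": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: str | Path, required: Sequence[str], allow_empty: bool = False) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if not allow_empty and df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def _parse_bool(v):
    if pd.isna(v) or v == "":
        return pd.NA
    if str(v).lower() in ("1", "true", "t", "yes"):
        return True
    if str(v).lower() in ("0", "false", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean flag {v!r}")
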