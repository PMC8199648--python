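"""Readers and writers for every external file format.

All tables are tab-delimited text.  Expression values are stored on the
log2 scale internally; linear inputs are transformed on read.  Writers use
a fixed float format and fixed row/column order so that two runs with
identical inputs produce byte-identical outputs.

No statistics live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

RNA_CLASSES = ("circRNA", "miRNA", "mRNA")
CIRC_TYPES = ("exonic", "intronic", "intergenic", "sense", "antisense")

#: clinical columns -> category, following the three phenotype groups
#: (tumor properties / invasion & metastasis / prognosis)
FEATURE_CATEGORY: dict[str, str] = {
    "size_group": "tumor_properties",
    "grade": "tumor_properties",
    "encapsulation": "tumor_properties",
    "degree_encapsulation": "tumor_properties",
    "vascular_invasion": "invasion_metastasis",
    "tumor_invasion": "invasion_metastasis",
    "stage_group": "prognosis",
    "survival": "prognosis",
}

CLINICAL_COLUMNS = (
    "patient_id",
    "sample_id",
    "tissue",
    "grade",
    "size_group",
    "encapsulation",
    "degree_encapsulation",
    "vascular_invasion",
    "tumor_invasion",
    "stage_group",
    "os_time",
    "os_event",
)


class FormatError(ValueError):
    """Malformed input file; the message locates the offending record."""


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Features x samples expression, stored on the log2 scale.

    ``values`` is a DataFrame with feature ids as index and sample ids as
    columns.  ``scale_flag`` records the scale of the file the matrix was
    read from ("log2" or "linear").
    """

    values: pd.DataFrame
    rna_class: str
    scale_flag: str = "log2"

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.rna_class, self.scale_flag)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)], self.rna_class, self.scale_flag)


def read_expression_matrix(
    path: str | Path,
    rna_class: str,
    scale: str = "log2",
    pseudocount: float = 1.0,
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a tab-delimited features x samples matrix.

    ``scale`` is "log2", "linear", or "auto" (linear if all values are
    non-negative and the maximum exceeds 50, a value no log2 microarray
    intensity reaches).  Linear values are mapped to log2(x + pseudocount).
    ``missing`` is "error" (any NaN aborts) or "drop" (rows with NaN are
    dropped; count logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[0]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.isna().any().any():
        n_bad = int(df.isna().any(axis=1).sum())
        if missing == "drop":
            log.info("read_expression_matrix: dropping %d rows with missing values", n_bad)
            df = df.dropna(axis=0)
        else:
            row = df.index[df.isna().any(axis=1)][0]
            raise FormatError(f"{path}: missing value in row {row!r} (missing_policy=error)")

    if scale == "auto":
        scale = "linear" if (df.values.min() >= 0 and df.values.max() > 50) else "log2"
    if scale == "linear":
        if (df.values < 0).any():
            raise FormatError(f"{path}: negative value in a matrix declared linear")
        df = np.log2(df + pseudocount)
    elif scale != "log2":
        raise ValueError(f"scale must be log2/linear/auto, got {scale!r}")

    log.info(
        "read_expression_matrix: %s %d features x %d samples (%s scale on file)",
        rna_class, df.shape[0], df.shape[1], scale,
    )
    return ExpressionMatrix(df, rna_class, scale_flag=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")


# ---------------------------------------------------------------------------
# clinical table


@dataclass
class ClinicalTable:
    """Per-sample clinical sheet for a paired tumor/non-tumor design."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("patient_id", "sample_id", "tissue") if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table lacks required columns {missing}")
        d = self.data
        if d["sample_id"].duplicated().any():
            dup = d.loc[d["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        bad_tissue = set(d["tissue"]) - {"tumor", "non_tumor"}
        if bad_tissue:
            raise FormatError(f"unknown tissue labels {sorted(bad_tissue)}")
        for pid, grp in d.groupby("patient_id"):
            counts = grp["tissue"].value_counts()
            if counts.get("tumor", 0) != 1 or counts.get("non_tumor", 0) != 1:
                raise FormatError(
                    f"patient {pid!r} does not have exactly one tumor and one "
                    f"non_tumor sample"
                )
        if "grade" in d.columns:
            g = d["grade"].dropna()
            bad = g[~g.isin([1, 2, 3, 4])]
            if len(bad):
                raise FormatError(f"grade value {bad.iloc[0]!r} outside 1-4")
        if "os_time" in d.columns:
            t = d["os_time"].dropna()
            if (t < 0).any():
                raise FormatError("negative os_time")
        if "os_event" in d.columns:
            e = d["os_event"].dropna()
            if not e.isin([0, 1]).all():
                raise FormatError("os_event must be 0/1")

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def sample_of(self, patient_id: str, tissue: str) -> str:
        d = self.data
        row = d[(d["patient_id"] == patient_id) & (d["tissue"] == tissue)]
        return row["sample_id"].iloc[0]

    def samples(self, tissue: str | None = None) -> list[str]:
        d = self.data
        if tissue is not None:
            d = d[d["tissue"] == tissue]
        return list(d["sample_id"])

    def paired_samples(self) -> tuple[list[str], list[str]]:
        """(tumor sample ids, matched non-tumor sample ids), patient-sorted."""
        tumor, normal = [], []
        for pid in self.patients:
            tumor.append(self.sample_of(pid, "tumor"))
            normal.append(self.sample_of(pid, "non_tumor"))
        return tumor, normal

    def patient_value(self, column: str) -> pd.Series:
        """Per-patient clinical value (taken from the tumor row), patient-indexed."""
        d = self.data[self.data["tissue"] == "tumor"].set_index("patient_id")
        return d.loc[self.patients, column]


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"patient_id": str, "sample_id": str})
    unknown = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    if unknown:
        log.warning("read_clinical_table: ignoring unknown columns %s", unknown)
        df = df.drop(columns=unknown)
    for col in ("grade", "size_group", "encapsulation", "degree_encapsulation",
                "vascular_invasion", "tumor_invasion", "stage_group", "os_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "os_time" in df.columns:
        df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in table.data.columns]
    table.data[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def check_samples_resolve(matrix: ExpressionMatrix, clinical: ClinicalTable) -> None:
    """Every matrix sample id must appear in the clinical sheet."""
    known = set(clinical.data["sample_id"])
    unknown = [s for s in matrix.sample_ids if s not in known]
    if unknown:
        raise FormatError(f"sample ids absent from clinical table: {unknown[:5]}")


# ---------------------------------------------------------------------------
# miRNA target table


DEFAULT_PREDICTOR_REGISTRY = ("miranda", "pita")


@dataclass
class TargetTable:
    """Predicted miRNA->target links with per-predictor provenance.

    ``data`` columns: mirna_id, target_id, target_class, predictors
    (a sorted tuple of predictor names).
    """

    data: pd.DataFrame
    registry: tuple[str, ...] = DEFAULT_PREDICTOR_REGISTRY

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["mirna_id", "target_id"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise FormatError(
                f"duplicate target record ({row['mirna_id']}, {row['target_id']})"
            )
        bad_class = set(self.data["target_class"]) - {"circRNA", "mRNA"}
        if bad_class:
            raise FormatError(f"unknown target_class {sorted(bad_class)}")
        reg = set(self.registry)
        for preds in self.data["predictors"]:
            extra = set(preds) - reg
            if extra:
                raise FormatError(f"predictors {sorted(extra)} not in registry {sorted(reg)}")

    def __len__(self) -> int:
        return len(self.data)


def read_target_table(
    path: str | Path, predictor_registry: Sequence[str] = DEFAULT_PREDICTOR_REGISTRY
) -> TargetTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    need = ["mirna_id", "target_id", "target_class", "predictors"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: target table lacks columns {missing}")
    df = df[need].copy()
    df["predictors"] = [
        tuple(sorted(p.split(","))) if isinstance(p, str) and p else ()
        for p in df["predictors"]
    ]
    return TargetTable(df, tuple(predictor_registry))


def write_target_table(table: TargetTable, path: str | Path) -> None:
    out = table.data.copy()
    out["predictors"] = [",".join(p) for p in out["predictors"]]
    out = out.sort_values(["mirna_id", "target_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# circRNA annotation


@dataclass
class CircAnnotation:
    """circRNA genomic annotation; coordinates 1-based inclusive."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["circ_id", "chrom", "start", "end", "strand", "host_gene", "circ_type"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise FormatError(f"annotation lacks columns {missing}")
        if (self.data["start"] > self.data["end"]).any():
            bad = self.data[self.data["start"] > self.data["end"]].iloc[0]
            raise FormatError(f"{bad['circ_id']}: start > end")
        bad_type = set(self.data["circ_type"]) - set(CIRC_TYPES)
        if bad_type:
            raise FormatError(f"unknown circ_type {sorted(bad_type)}")


def read_circ_annotation(path: str | Path) -> CircAnnotation:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"circ_id": str, "host_gene": str})
    df["start"] = pd.to_numeric(df["start"]).astype(int)
    df["end"] = pd.to_numeric(df["end"]).astype(int)
    return CircAnnotation(df)


# ---------------------------------------------------------------------------
# network export


def write_network(
    nodes: Mapping[str, Mapping[str, object]],
    edges: Iterable[tuple[str, str, str] | tuple[str, str, str, Mapping[str, object]]],
    path: str | Path,
    fmt: str = "sif",
) -> None:
    """Write a network for Cytoscape import.

    ``nodes`` maps node id -> attribute dict; ``edges`` yields
    (source, relation, target[, attrs]).  SIF carries only the triples;
    GraphML carries node and edge attributes.  Output order is sorted, so
    identical input gives byte-identical files.
    """
    edges = list(edges)
    if fmt == "sif":
        lines = sorted(f"{e[0]}\t{e[1]}\t{e[2]}" for e in edges)
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for nid in sorted(nodes):
            g.add_node(nid, **{k: _gml_scalar(v) for k, v in sorted(nodes[nid].items())})
        for e in sorted(edges, key=lambda e: (e[0], e[2], e[1])):
            attrs = dict(e[3]) if len(e) > 3 else {}
            attrs["relation"] = e[1]
            g.add_edge(e[0], e[2], **{k: _gml_scalar(v) for k, v in sorted(attrs.items())})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _gml_scalar(v: object) -> object:
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (str, int, float, bool)):
        return v
    return str(v)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump used by every stage (fixed float format)."""
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0)
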