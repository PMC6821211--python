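"""Readers, writers and validated containers for the pipeline's file formats.

Signatures travel as GCT 1.3 text (genes in rows, perturbation instances in
columns, the de facto container for landmark-gene signature matrices); tabular
inputs (viability, annotations, drug sensitivity, baseline sidecars) are plain
TSV with documented headers.  All matrices are dense: the gene space is the
~1000 landmark genes, so sparsity buys nothing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "SignatureSet",
    "ViabilityTable",
    "AnnotationTable",
    "read_signature_gct",
    "write_signature_gct",
    "read_tables",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

PERTURBAGEN_TYPES = ("compound", "shRNA", "control")

#: instance metadata fields stored in the GCT column-metadata block
INSTANCE_META_FIELDS = ("cell_line_id", "perturbagen_id", "perturbagen_type",
                       "dose_um", "time_h")
GENE_META_FIELDS = ("gene_symbol",)


class FormatError(ValueError):
    """Malformed file: bad header, dimension mismatch, unparsable cell."""


class SchemaError(ValueError):
    """A table does not satisfy its declared schema or invariants."""


@dataclass
class SignatureSet:
    """Matrix of differential-expression z-scores with instance/gene metadata.

    ``values`` is instances x genes (index = instance_id, columns = gene_id).
    ``row_meta`` is indexed by instance_id and carries cell_line_id,
    perturbagen_id, perturbagen_type, dose_um (NaN for shRNA/control) and
    time_h.  ``col_meta`` is indexed by gene_id and carries gene_symbol.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise SchemaError("signature values must all be finite")
        if v.index.has_duplicates:
            raise SchemaError("instance_ids must be unique")
        if v.columns.has_duplicates:
            raise SchemaError("gene_ids must be unique")
        if not v.index.equals(self.row_meta.index):
            raise SchemaError("row_meta index must equal the instance axis")
        if not v.columns.equals(self.col_meta.index):
            raise SchemaError("col_meta index must equal the gene axis")
        for col in INSTANCE_META_FIELDS:
            if col not in self.row_meta.columns:
                raise SchemaError(f"row_meta missing field {col!r}")
        ptype = self.row_meta["perturbagen_type"]
        bad = ~ptype.isin(PERTURBAGEN_TYPES) & ptype.notna()
        if bad.any():
            raise SchemaError(
                f"unknown perturbagen_type values: {sorted(ptype[bad].unique())}")
        dose = pd.to_numeric(self.row_meta["dose_um"], errors="coerce")
        is_compound = ptype == "compound"
        if (is_compound & dose.isna()).any():
            raise SchemaError("compound instances must carry a dose")
        if (~is_compound & ptype.notna() & dose.notna()).any():
            raise SchemaError("dose is only meaningful for compound instances")

    # -- convenience --------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, mask) -> "SignatureSet":
        return SignatureSet(self.values.loc[mask], self.row_meta.loc[mask],
                            self.col_meta)

    def subset_genes(self, genes) -> "SignatureSet":
        return SignatureSet(self.values.loc[:, genes],
                            self.row_meta, self.col_meta.loc[genes])

    @staticmethod
    def from_values(values: pd.DataFrame, row_meta: pd.DataFrame | None = None,
                    col_meta: pd.DataFrame | None = None) -> "SignatureSet":
        """Build a set, defaulting any absent metadata fields."""
        if row_meta is None:
            row_meta = pd.DataFrame(index=values.index)
        else:
            row_meta = row_meta.copy()
        for f in INSTANCE_META_FIELDS:
            if f not in row_meta.columns:
                row_meta[f] = np.nan
        if col_meta is None:
            col_meta = pd.DataFrame(index=values.columns)
        else:
            col_meta = col_meta.copy()
        if "gene_symbol" not in col_meta.columns:
            col_meta["gene_symbol"] = col_meta.index
        return SignatureSet(values, row_meta, col_meta)


@dataclass
class ViabilityTable:
    """Per (cell, perturbagen[, dose]) viability outcomes with one metric type.

    ``metric_type`` is ``"fraction"`` (percent-viability screens, values >= 0)
    or ``"log_fold_change"`` (pooled shRNA abundance screens).
    """

    records: pd.DataFrame

    REQUIRED = ("cell_line_id", "perturbagen_id", "viability", "metric_type")

    def __post_init__(self) -> None:
        df = self.records
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"viability table missing column {col!r}")
        if "dose_um" not in df.columns:
            df = df.assign(dose_um=np.nan)
        if "assay_time_h" not in df.columns:
            df = df.assign(assay_time_h=np.nan)
        self.records = df.reset_index(drop=True)
        metrics = set(df["metric_type"].unique())
        if len(metrics) > 1:
            raise SchemaError(f"metric_type must be uniform, got {sorted(metrics)}")
        if metrics and not metrics <= {"fraction", "log_fold_change"}:
            raise SchemaError(f"unknown metric_type {sorted(metrics)}")
        if self.metric_type == "fraction" and (df["viability"] < 0).any():
            raise SchemaError("fraction viability values must be >= 0")
        keys = df[["cell_line_id", "perturbagen_id", "dose_um"]]
        if keys.duplicated().any():
            raise SchemaError("duplicate (cell, perturbagen, dose) keys")

    @property
    def metric_type(self) -> str | None:
        m = self.records["metric_type"].unique()
        return m[0] if len(m) else None


@dataclass
class AnnotationTable:
    """MoA/target labels per perturbagen, with optional fingerprints.

    ``frame`` is indexed by perturbagen_id with columns: ``labels``
    (frozenset of non-empty strings), optional ``fingerprint`` (uint8 array,
    one common length) and optional ``max_tested_log10_conc``.
    """

    frame: pd.DataFrame
    n_bits: int | None = field(default=None)

    def __post_init__(self) -> None:
        if "labels" not in self.frame.columns:
            raise SchemaError("annotation table missing 'labels'")
        for pid, labels in self.frame["labels"].items():
            if any((not isinstance(l, str)) or not l for l in labels):
                raise SchemaError(f"empty/non-string label for {pid!r}")
        if "fingerprint" in self.frame.columns:
            lengths = {len(fp) for fp in self.frame["fingerprint"].dropna()}
            if len(lengths) > 1:
                raise SchemaError(f"fingerprint lengths differ: {sorted(lengths)}")
            if lengths and self.n_bits is None:
                self.n_bits = lengths.pop()

    def labels_of(self, perturbagen_id: str) -> frozenset:
        return self.frame.at[perturbagen_id, "labels"]

    def shared_moa(self, a: str, b: str) -> bool:
        return bool(self.labels_of(a) & self.labels_of(b))


# ---------------------------------------------------------------------------
# GCT 1.3
# ---------------------------------------------------------------------------

def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: line {lineno}: cannot parse {token!r} as a number") from None


def read_signature_gct(path) -> SignatureSet:
    """Read a GCT 1.3 text file into a :class:`SignatureSet`.

    The file stores genes in rows and instances in columns; the returned set
    is transposed to the pipeline's instances x genes orientation.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.3":
        raise FormatError(f"{path}: line 1: expected version line '#1.3'")
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated file, no dimension line")
    dims = lines[1].split("\t")
    if len(dims) != 4:
        raise FormatError(f"{path}: line 2: dimension line needs 4 fields")
    try:
        n_genes, n_inst, n_rmeta, n_cmeta = (int(x) for x in dims)
    except ValueError:
        raise FormatError(f"{path}: line 2: non-integer dimensions") from None

    header = lines[2].split("\t")
    if len(header) != 1 + n_rmeta + n_inst:
        raise FormatError(
            f"{path}: line 3: expected {1 + n_rmeta + n_inst} header fields, "
            f"got {len(header)}")
    rmeta_names = header[1:1 + n_rmeta]
    instance_ids = header[1 + n_rmeta:]

    cmeta: dict[str, list[str]] = {}
    for i in range(n_cmeta):
        lineno = 4 + i
        if 3 + i >= len(lines):
            raise FormatError(f"{path}: line {lineno}: missing column-metadata row")
        parts = lines[3 + i].split("\t")
        if len(parts) != 1 + n_rmeta + n_inst:
            raise FormatError(f"{path}: line {lineno}: wrong field count")
        cmeta[parts[0]] = parts[1 + n_rmeta:]

    data_lines = [l for l in lines[3 + n_cmeta:] if l.strip()]
    if len(data_lines) != n_genes:
        raise FormatError(
            f"{path}: declared {n_genes} data rows, found {len(data_lines)} "
            f"(first data line is line {4 + n_cmeta})")
    gene_ids, rmeta_rows, data_rows = [], [], []
    for i, line in enumerate(data_lines):
        lineno = 4 + n_cmeta + i
        parts = line.split("\t")
        if len(parts) != 1 + n_rmeta + n_inst:
            raise FormatError(f"{path}: line {lineno}: wrong field count")
        gene_ids.append(parts[0])
        rmeta_rows.append(parts[1:1 + n_rmeta])
        data_rows.append([_parse_float(t, path, lineno)
                          for t in parts[1 + n_rmeta:]])

    values = pd.DataFrame(np.asarray(data_rows, dtype=float).T,
                          index=pd.Index(instance_ids, name="instance_id"),
                          columns=pd.Index(gene_ids, name="gene_id"))
    col_meta = pd.DataFrame(rmeta_rows, index=values.columns,
                            columns=rmeta_names)
    if "gene_symbol" not in col_meta.columns:
        col_meta["gene_symbol"] = col_meta.index
    row_meta = pd.DataFrame(index=values.index)
    for name in INSTANCE_META_FIELDS:
        raw = cmeta.get(name, ["na"] * n_inst)
        if name in ("dose_um", "time_h"):
            row_meta[name] = [np.nan if t in ("na", "", "NA", "-666")
                              else float(t) for t in raw]
        else:
            row_meta[name] = [None if t in ("na", "", "NA", "-666") else t
                              for t in raw]
    return SignatureSet(values, row_meta, col_meta)


def write_signature_gct(sigset: SignatureSet, path) -> None:
    """Write a :class:`SignatureSet` as GCT 1.3 text (round-trip exact)."""
    sigset.validate()
    buf = io.StringIO()
    n_inst, n_genes = sigset.values.shape
    rmeta = sigset.col_meta.reindex(columns=list(GENE_META_FIELDS))
    rmeta = rmeta.fillna({"gene_symbol": ""})
    buf.write("#1.3\n")
    buf.write(f"{n_genes}\t{n_inst}\t{rmeta.shape[1]}\t{len(INSTANCE_META_FIELDS)}\n")
    buf.write("\t".join(["id", *rmeta.columns, *map(str, sigset.values.index)]))
    buf.write("\n")
    for name in INSTANCE_META_FIELDS:
        vals = sigset.row_meta[name]
        toks = []
        for v in vals:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                toks.append("na")
            elif name in ("dose_um", "time_h"):
                toks.append(repr(float(v)))
            else:
                toks.append(str(v))
        buf.write("\t".join([name, *["na"] * rmeta.shape[1], *toks]) + "\n")
    mat = sigset.values.to_numpy(dtype=float).T
    for i, gid in enumerate(sigset.values.columns):
        row_toks = [str(gid), *map(str, rmeta.iloc[i])]
        row_toks.extend(repr(float(x)) for x in mat[i])
        buf.write("\t".join(row_toks) + "\n")
    with open(str(path), "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_TABLE_SCHEMAS = {
    "viability": ("cell_line_id", "perturbagen_id", "viability", "metric_type"),
    "annotation": ("perturbagen_id", "labels"),
    "sensitivity": ("cell_line_id", "drug_id"),
    "baseline": ("cell_line_id", "tissue"),
}


def read_tables(path, schema: str):
    """Read a TSV with one of the declared schemas into its typed container.

    Schemas: ``viability`` -> :class:`ViabilityTable`; ``annotation`` ->
    :class:`AnnotationTable` (labels ';'-delimited, fingerprints as 0/1
    strings); ``sensitivity`` -> DataFrame with at least one of auc/ln_ic50;
    ``baseline`` -> the cell-line sidecar DataFrame (tissue, msi,
    doubling_time_h).  Unknown columns are preserved.
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(str(path), sep="\t", dtype={"fingerprint": str})
    missing = [c for c in _TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} missing columns {missing}")

    if schema == "viability":
        if "dose_um" in df.columns:
            df["dose_um"] = pd.to_numeric(df["dose_um"], errors="coerce")
        return ViabilityTable(df)
    if schema == "annotation":
        frame = df.set_index("perturbagen_id")
        frame["labels"] = [
            frozenset(s for s in str(x).split(";") if s)
            for x in frame["labels"]
        ]
        if "fingerprint" in frame.columns:
            frame["fingerprint"] = [
                np.array([int(c) for c in str(b)], dtype=np.uint8)
                for b in frame["fingerprint"]
            ]
        return AnnotationTable(frame)
    if schema == "sensitivity":
        if not ({"auc", "ln_ic50"} & set(df.columns)):
            raise SchemaError(f"{path}: sensitivity table needs auc or ln_ic50")
        return df
    return df  # baseline sidecar


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a genes x cell-lines expression matrix TSV (first column = gene_id)."""
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise SchemaError(f"{path}: duplicate gene ids")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(str(path), sep="\t")
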