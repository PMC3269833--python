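"""Readers and writers for expression matrices and the pipeline's tables.

Expression matrices are genes x samples (microarray convention), log2
scale, tab-delimited text or GCT 1.2.  Missing values are "NA" or an
empty cell in TSV, an empty cell in GCT.  Results tables are written
deterministically (fixed column and row order, 6 significant digits) with
a provenance header comment recording tool version, seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_annotations",
    "read_pairs",
    "write_results",
    "read_results",
    "config_hash",
]

_NA_TOKENS = ("NA", "")


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with unique identifiers.

    ``data`` is a float DataFrame indexed by gene_id with sample_id
    columns; NaN marks missing values.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.data.index.duplicated().any():
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        self.data = self.data.astype(float)
        self.data.index.name = "gene_id"
        self.data.columns.name = None
        values = self.data.to_numpy()
        if np.isinf(values).any():
            raise ValidationError("expression values must be finite or missing (NA)")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)


def _parse_numeric_block(frame: pd.DataFrame, path) -> pd.DataFrame:
    """Convert a string-typed block to floats, locating any bad cell."""
    raw = frame.astype(str).apply(lambda col: col.str.strip())
    is_na = raw.isin(_NA_TOKENS) | frame.isna()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_na
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return numeric.where(~is_na)


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    ``format`` is "tsv" or "gct"; inferred from the file extension when
    omitted.  TSV: first column gene identifiers, header row sample
    identifiers.  GCT 1.2: "#1.2" version line, a dimensions line, then a
    table whose first two columns are Name and Description.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    elif fmt == "gct":
        with open(path) as handle:
            version = handle.readline().strip()
            if version != "#1.2":
                raise ValidationError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = handle.readline().split()
            if len(dims) != 2:
                raise ValidationError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            frame = pd.read_csv(handle, sep="\t", index_col=0, dtype=str)
        frame = frame.drop(columns=frame.columns[0])  # Description column
        if frame.shape != (n_genes, n_samples):
            raise ValidationError(
                f"{path}: GCT declares {n_genes} x {n_samples} but table is "
                f"{frame.shape[0]} x {frame.shape[1]}"
            )
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    if frame.index.duplicated().any():
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene identifiers: {dupes}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(_parse_numeric_block(frame, path), provenance=str(path))


def write_expression(matrix: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a matrix as TSV (gene_id first column) or GCT 1.2."""
    path = Path(path)
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    frame = matrix.data
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA", lineterminator="\n")
    elif fmt == "gct":
        with open(path, "w", newline="\n") as handle:
            handle.write("#1.2\n")
            handle.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
            out = frame.copy()
            out.insert(0, "Description", "na")
            out.to_csv(handle, sep="\t", index_label="Name", na_rep="", lineterminator="\n")
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, phenotype, ...)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id",):
        if col not in table.columns:
            raise SchemaError(f"{path}: annotation table missing column {col!r}")
    if table["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in annotations")
    return table.set_index("sample_id")


def read_pairs(path) -> pd.DataFrame:
    """Read a pairing table (pair_id, tumor_sample, normal_sample)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"pairing file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("pair_id", "tumor_sample", "normal_sample"):
        if col not in table.columns:
            raise SchemaError(f"{path}: pairing table missing column {col!r}")
    if table["pair_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate pair_id in pairing table")
    return table


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping, for provenance headers."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _format_value(value) -> str:
    if not isinstance(value, str) and pd.isna(value):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    return str(value)


def write_results(
    table: pd.DataFrame,
    path,
    required_columns: Iterable[str] | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a results table deterministically with a provenance header.

    Rows are ordered by rank then gene_id when those columns exist; floats
    use 6 significant digits.  Missing required columns raise SchemaError.
    """
    from . import __version__

    if required_columns:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise SchemaError(f"results table missing required column(s): {missing}")
    out = table.copy()
    sort_cols = [c for c in ("rank", "gene_id") if c in out.columns]
    if sort_cols:
        out = out.sort_values(sort_cols, kind="mergesort")
    header = (
        f"# switchscan {__version__} seed={'NA' if seed is None else seed} "
        f"config_sha256={config_hash(config)}\n"
    )
    with open(path, "w", newline="\n") as handle:
        handle.write(header)
        handle.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            handle.write("\t".join(_format_value(v) for v in row) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
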