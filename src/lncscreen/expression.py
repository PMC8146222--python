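"""Expression-matrix ingestion, validation, filtering and transforms.

The canonical in-memory container is a pandas DataFrame with gene
identifiers as the index and sample identifiers as the columns, holding
nonnegative FPKM values.  Gene annotation is a DataFrame indexed by
``gene_id`` with columns ``symbol``, ``biotype`` and ``chromosome``,
where ``biotype`` is one of ``{"lncRNA", "mRNA", "other"}``.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

BIOTYPES = ("lncRNA", "mRNA", "other")

#: GENCODE-style ``gene_type`` values collapsed to the three-way biotype
#: used throughout the screen.  Anything absent from this table is "other".
GENE_TYPE_MAP = {
    "protein_coding": "mRNA",
    "lncRNA": "lncRNA",
    # older GENCODE releases spell out the long non-coding classes
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
}


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples FPKM matrix and return it unchanged.

    Checks: unique gene and sample identifiers, all values finite,
    numeric and >= 0.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("expression matrix is empty")
    dup = matrix.index[matrix.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate gene id(s): {', '.join(map(str, dup[:5]))}")
    dup = matrix.columns[matrix.columns.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate sample id(s): {', '.join(map(str, dup[:5]))}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = matrix.map(lambda v: not isinstance(v, (int, float)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value at gene {matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"negative or non-finite value {values[r, c]!r} at gene "
            f"{matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )
    return matrix


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated genes x samples FPKM table.

    First column holds gene identifiers, the header row sample
    identifiers.  Lines starting with ``#`` (provenance headers written
    by this package) are ignored.  Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return validate_expression(df)


def write_expression_table(matrix: pd.DataFrame, path: str | Path,
                           header_lines: Iterable[str] = ()) -> None:
    """Write a matrix in the TSV dialect `read_expression_table` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read gene annotation from a GENCODE-style GTF or a flat TSV.

    The TSV dialect expects columns ``gene_id``, ``symbol``, ``biotype``,
    ``chromosome``.  The GTF dialect parses only ``gene`` feature lines
    and maps ``gene_type`` through :data:`GENE_TYPE_MAP`.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        missing = {"gene_id", "symbol", "biotype", "chromosome"} - set(df.columns)
        if missing:
            raise ValidationError(f"annotation TSV missing column(s): {sorted(missing)}")
        df = df.set_index("gene_id")[["symbol", "biotype", "chromosome"]]
    elif dialect == "gtf":
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValidationError(f"{path}:{lineno}: fewer than 9 GTF fields")
                if fields[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                try:
                    gene_id = attrs["gene_id"]
                except KeyError:
                    raise ValidationError(
                        f"{path}:{lineno}: gene feature without gene_id attribute"
                    ) from None
                biotype = GENE_TYPE_MAP.get(attrs.get("gene_type", ""), "other")
                records.append(
                    (gene_id, attrs.get("gene_name", gene_id), biotype, fields[0])
                )
        df = pd.DataFrame(
            records, columns=["gene_id", "symbol", "biotype", "chromosome"]
        ).set_index("gene_id")
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"duplicate gene id(s) in annotation: {list(dup[:5])}")
    bad = set(df["biotype"]) - set(BIOTYPES)
    if bad:
        raise ValidationError(f"biotype value(s) outside {BIOTYPES}: {sorted(bad)}")
    return df


def filter_expressed(matrix: pd.DataFrame, min_value: float = 0.1,
                     min_fraction: float = 0.25) -> tuple[pd.DataFrame, pd.Series]:
    """Keep genes detected at ``>= min_value`` in ``>= min_fraction`` of samples.

    Both comparisons are inclusive: a gene at FPKM exactly ``min_value``
    in exactly ``min_fraction`` of the samples is retained.  Returns the
    filtered matrix and the boolean kept-mask over the input gene index.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    validate_expression(matrix)
    frac = (matrix.to_numpy() >= min_value).mean(axis=1)
    mask = pd.Series(frac >= min_fraction, index=matrix.index, name="expressed")
    return matrix.loc[mask], mask


def restrict_biotypes(matrix: pd.DataFrame, annotation: pd.DataFrame,
                      keep: frozenset[str] | set[str] = frozenset({"lncRNA", "mRNA"}),
                      strict: bool = True) -> pd.DataFrame:
    """Restrict a matrix to genes whose annotated biotype is in ``keep``.

    Under ``strict`` (default) a matrix gene absent from the annotation is
    an error; otherwise unannotated genes are dropped.
    """
    unknown = matrix.index.difference(annotation.index)
    if len(unknown):
        if strict:
            raise ValidationError(
                f"gene(s) missing from annotation: {list(unknown[:5])}"
            )
        matrix = matrix.drop(index=unknown)
    biotype = annotation.loc[matrix.index, "biotype"]
    return matrix.loc[biotype.isin(keep)]


def log_transform(matrix: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Map each FPKM value x to log_base(x + 1).

    Monotone, zero-preserving; the downstream correlation network is
    invariant to the base (a change of base rescales every value by the
    same positive constant).
    """
    if base <= 0 or base == 1:
        raise ValueError("logarithm base must be positive and != 1")
    validate_expression(matrix)
    return pd.DataFrame(
        np.log1p(matrix.to_numpy()) / math.log(base),
        index=matrix.index, columns=matrix.columns,
    )


def max_normalize_per_gene(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each gene row by its maximum so every nonzero row peaks at 1.

    All-zero rows pass through unchanged; the returned flag series marks
    them.  This is the per-gene scaling used when comparing a gene's
    profile across cell types.
    """
    validate_expression(matrix)
    values = matrix.to_numpy(dtype=float).copy()
    rowmax = values.max(axis=1)
    zero = rowmax == 0
    safe = np.where(zero, 1.0, rowmax)
    out = pd.DataFrame(values / safe[:, None], index=matrix.index,
                       columns=matrix.columns)
    return out, pd.Series(zero, index=matrix.index, name="all_zero")
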