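"""Differential-expression ingestion and a built-in two-group test.

Real datasets arrive as result tables from dedicated DE tools; this
module only applies the significance contract (adjusted p <= threshold,
inclusive) and derives a direction from the effect sign.  For fully
synthetic runs a Welch t-test on log2(FPKM + 1) with Benjamini-Hochberg
adjustment stands in, so the end-to-end screen needs no external tool;
its output metadata labels it as the built-in test.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ValidationError, validate_expression

DEFAULT_COLUMNS = {"gene_id": "gene_id", "effect": "log2FoldChange",
                   "p": "pvalue", "adj_p": "padj"}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"


def load_de_results(path: str | Path, adj_p_threshold: float = 0.05,
                    columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a DE result table and flag the significant rows.

    Returns a DataFrame indexed by gene id with columns ``effect``
    (log2 fold change), ``p``, ``adj_p``, ``significant`` (adjusted
    p <= threshold, boundary inclusive) and ``direction`` (``up_in_A``
    for positive effect, ``up_in_B`` otherwise — A being the effect's
    reference numerator).
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    raw = pd.read_csv(path, sep="\t", comment="#")
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValidationError(f"DE table missing column(s): {missing}")
    out = pd.DataFrame({
        "effect": raw[colmap["effect"]].to_numpy(dtype=float),
        "p": raw[colmap["p"]].to_numpy(dtype=float),
        "adj_p": raw[colmap["adj_p"]].to_numpy(dtype=float),
    }, index=pd.Index(raw[colmap["gene_id"]].astype(str), name="gene_id"))
    for col in ("p", "adj_p"):
        bad = out[col].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError(f"column {col!r} has values outside [0, 1]")
    out["significant"] = out["adj_p"] <= adj_p_threshold
    out["direction"] = np.where(out["effect"] > 0, UP_IN_A, UP_IN_B)
    return out


def simple_de_test(matrix: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on log2(FPKM + 1).

    ``groups`` maps every sample to "A" or "B" (>= 2 samples each).  The
    effect is the difference of group means of log2(FPKM + 1), A minus
    B; p-values are Benjamini-Hochberg adjusted across all tested genes.
    """
    validate_expression(matrix)
    groups = pd.Series(groups)
    a_cols = [s for s in matrix.columns if groups.get(s) == "A"]
    b_cols = [s for s in matrix.columns if groups.get(s) == "B"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    log = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    ia = [matrix.columns.get_loc(s) for s in a_cols]
    ib = [matrix.columns.get_loc(s) for s in b_cols]
    xa, xb = log[:, ia], log[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant and equal
    adj = bh_adjust(p)
    effect = xa.mean(axis=1) - xb.mean(axis=1)
    out = pd.DataFrame({
        "effect": effect, "p": p, "adj_p": adj,
        "direction": np.where(effect > 0, UP_IN_A, UP_IN_B),
    }, index=matrix.index)
    out.attrs["method"] = "built-in Welch t / BH (synthetic runs only)"
    return out


def combine_gene_sets(a, b, op: str = "union") -> set:
    """Exact set algebra on gene id collections."""
    a, b = set(a), set(b)
    if op == "union":
        return a | b
    if op == "intersection":
        return a & b
    raise ValueError("op must be 'union' or 'intersection'")


def intersect_with_annotation_list(genes, curated) -> set:
    """Intersection with a caller-supplied curated gene list
    (e.g. an ontology-derived list of differentiation genes)."""
    return set(genes) & set(curated)
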