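"""Small packaged reference tables from the published CSH3 screen.

Two tables ship with the package as plain TSV:

* ``candidate_lncrnas()`` — the 14 lncRNAs that are both co-expression
  hubs (essential) and differentially expressed between normally
  differentiating and differentiation-arrested CSH3 cells, with their
  scaled intramodular degree, the condition they are enriched in, and
  the reported adjusted p-value of the differential call.
* ``tf_correlations()`` — Pearson correlations of 19 transcription
  factors with the lncRNA Gdal1 across a 6-point nascent-transcription
  time course (0-72 h of granulocytic differentiation), with the
  reported correlation-test p-values.  The target gene itself heads the
  table with r = 1.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("lncscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def candidate_lncrnas() -> pd.DataFrame:
    """14 candidate lncRNAs (index gene_id; columns symbol, chromosome,
    scaled_degree, enriched_in in {normal_diff, diff_arrest}, adj_p)."""
    return _load("csh3_candidate_lncrnas.tsv")


def tf_correlations(include_target: bool = False) -> pd.DataFrame:
    """19 TF-vs-target correlations (index gene_id; columns symbol, r, p).

    ``include_target`` keeps the target gene's own r = 1 row.
    """
    df = _load("gdal1_tf_correlations.tsv")
    return df if include_target else df.iloc[1:]
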