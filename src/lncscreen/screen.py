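"""Essentiality ranking and the candidate-lncRNA screen.

A gene is called "essential" when its intramodular connectivity ranks
in the top quarter of its module — hubs of a co-expression module tend
to sit in the pathways the module represents.  Essential lncRNAs are
then intersected with differentially expressed lncRNAs to produce the
candidate table, and gene sets can be tested for annotation-term
over-representation with the Fisher exact test.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import GREY


def essential_genes(assignment: pd.Series, kim: pd.Series,
                    scaled: pd.Series | None = None,
                    top_fraction: float = 0.25) -> pd.DataFrame:
    """Select the top ``top_fraction`` of each module by intramodular degree.

    Per non-grey module, ceil(top_fraction x module size) genes with the
    highest kIM are selected; ties go to the higher scaled degree, then
    the lexicographically smaller gene id.  Grey genes are ineligible:
    grey is a catch-all for unassigned genes, not a module.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if scaled is None:
        from .network import scaled_intramodular_degree
        scaled = scaled_intramodular_degree(kim, assignment)
    rows = []
    for label in sorted(set(assignment.unique()) - {GREY}):
        members = assignment.index[assignment == label]
        n_take = math.ceil(top_fraction * len(members))
        ranked = sorted(
            members,
            key=lambda g: (-kim[g], -scaled[g], g),
        )
        for g in ranked[:n_take]:
            rows.append((g, label, float(kim[g]), float(scaled[g])))
    return pd.DataFrame(rows, columns=["gene_id", "module", "kIM",
                                       "scaled_degree"]).set_index("gene_id")


def biotype_partition(essential: pd.DataFrame,
                      annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-biotype essential counts and shares of the expressed universe.

    ``annotation`` must cover exactly the expressed genes: the reported
    percentage is (essential of that biotype) / (expressed of that
    biotype), rounded to one decimal.
    """
    missing = essential.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"unannotated essential gene(s): {list(missing[:5])}")
    expressed = annotation["biotype"].value_counts()
    ess = annotation.loc[essential.index, "biotype"].value_counts()
    rows = []
    for biotype in ("mRNA", "lncRNA", "other"):
        n_exp = int(expressed.get(biotype, 0))
        n_ess = int(ess.get(biotype, 0))
        pct = round(100.0 * n_ess / n_exp, 1) if n_exp else 0.0
        rows.append((biotype, n_ess, n_exp, pct))
    return pd.DataFrame(rows, columns=["biotype", "n_essential",
                                       "n_expressed", "pct_of_expressed"]
                        ).set_index("biotype")


def essential_fraction_pct(n_essential: int, n_expressed: int) -> float:
    """Share of an expressed gene class called essential, as a percentage
    rounded to one decimal (e.g. 1862 of 13,804 coding genes -> 13.5)."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    return round(100.0 * n_essential / n_expressed, 1)


def chromosome_distribution(gene_set, annotation: pd.DataFrame,
                            chrom_sizes: dict[str, int],
                            subset: list[str]) -> tuple[float, float]:
    """Fractions (as percentages, 1 decimal) of genes and of genome length
    falling on a chromosome subset.

    Used to ask whether a gene class concentrates on part of the genome
    beyond what sheer chromosome length predicts.
    """
    gene_set = list(gene_set)
    chroms = annotation.loc[gene_set, "chromosome"]
    missing = set(chroms) - set(chrom_sizes)
    if missing:
        raise ValueError(f"chromosome(s) without a size entry: {sorted(missing)}")
    subset_set = set(subset)
    gene_pct = round(100.0 * chroms.isin(subset_set).mean(), 1) if gene_set else 0.0
    total = sum(chrom_sizes.values())
    on_subset = sum(v for c, v in chrom_sizes.items() if c in subset_set)
    genome_pct = round(100.0 * on_subset / total, 1)
    return gene_pct, genome_pct


def overlap_candidates(essential_lnc: pd.DataFrame, de_table: pd.DataFrame,
                       annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Intersect essential lncRNAs with differentially expressed lncRNAs.

    ``essential_lnc`` is an essential-gene table restricted to lncRNAs
    (index gene_id, columns module/kIM/scaled_degree); ``de_table`` is a
    significant DE table (index gene_id, columns including ``adj_p`` and
    ``direction``).  One candidate record per shared gene, sorted by
    ascending adjusted p.
    """
    shared = essential_lnc.index.intersection(de_table.index)
    out = essential_lnc.loc[shared, ["module", "kIM", "scaled_degree"]].copy()
    out["adj_p"] = de_table.loc[shared, "adj_p"]
    out["enriched_in"] = de_table.loc[shared, "direction"]
    if annotation is not None:
        out["symbol"] = annotation.loc[shared, "symbol"]
        out["chromosome"] = annotation.loc[shared, "chromosome"]
    # stable sort on adj_p after an index sort -> deterministic tie order
    return out.sort_index().sort_values("adj_p", kind="mergesort")


def fisher_enrichment(study: set, population: set,
                      term2genes: dict[str, set],
                      adjust: str = "BH",
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-term over-representation p-values by the Fisher exact test.

    For each term the 2x2 table (study hits, study misses, background
    hits, background misses) is tested one-sided for over-representation
    (``alternative='greater'``, the gene-set enrichment convention;
    ``'two-sided'`` available).  Term gene sets are intersected with the
    population first, and Benjamini-Hochberg adjustment is applied when
    ``adjust='BH'``.
    """
    population = set(population)
    if not population:
        raise ValueError("population must be nonempty")
    study = set(study)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    rows = []
    for term in sorted(term2genes):
        hits = term2genes[term] & population
        k = len(hits & study)
        table = [[k, len(study) - k],
                 [len(hits) - k, len(population) - len(study) - len(hits) + k]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        rows.append((term, k, len(study), len(hits), len(population), float(p)))
    out = pd.DataFrame(rows, columns=["term", "study_hits", "study_size",
                                      "population_hits", "population_size", "p"])
    if adjust not in ("BH", "none"):
        raise ValueError("adjust must be 'BH' or 'none'")
    if adjust == "BH" and len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["adj_p"] = out["p"]
    return out.set_index("term")
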