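"""Signed weighted co-expression network construction.

Given a log-expression matrix the steps are: Pearson correlation across
samples, signed soft-threshold adjacency a_ij = ((1 + cor_ij) / 2)^beta,
soft-power selection by the scale-free topology fit, the topological
overlap matrix (TOM) and its dissimilarity, and weighted connectivity
(whole-network and intramodular).

All matrices are dense pandas DataFrames sharing one gene index on both
axes.  Diagonals of adjacency and TOM are fixed at 1 by convention;
every connectivity sum excludes the self term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GREY = "grey"


def correlation_matrix(logmat: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples.

    Zero-variance genes cannot be correlated; under ``strict`` they raise,
    otherwise they are dropped with the reduced matrix returned.
    """
    if logmat.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    sd = logmat.to_numpy().std(axis=1)
    flat = logmat.index[sd == 0]
    if len(flat):
        if strict:
            raise ValueError(f"zero-variance gene(s): {list(flat[:5])}")
        logmat = logmat.drop(index=flat)
    cor = np.atleast_2d(np.corrcoef(logmat.to_numpy()))
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=logmat.index, columns=logmat.index)


def signed_adjacency(cor: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta, diagonal 1.

    Positive correlation maps toward 1 and negative toward 0, so the
    network distinguishes the sign of co-expression; raising to the soft
    power beta suppresses weak edges while keeping the network weighted.
    """
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    adj = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology fit for one soft power.

    ``fit_index`` is the signed R^2 of the log-log regression of the
    binned connectivity distribution: positive when the degree
    distribution decreases (slope < 0), negative otherwise.
    """
    power: int
    fit_index: float
    slope: float


class DegenerateDegreeDistribution(ValueError):
    pass


def scale_free_fit(k: np.ndarray, n_bins: int = 10, power: int = 0) -> ScaleFreeFit:
    """Signed scale-free model fit of a connectivity vector.

    Connectivities are placed in ``n_bins`` equal-width bins; the log10
    relative frequency per bin is regressed on the log10 mean
    connectivity per bin over usable bins (nonempty, mean k > 0).
    """
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("connectivities must be nonnegative")
    lo, hi = k.min(), k.max()
    if hi <= lo:
        raise DegenerateDegreeDistribution("degenerate degree distribution")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    usable = counts > 0
    mean_k = np.where(usable, sums / np.maximum(counts, 1), 0.0)
    usable &= mean_k > 0
    if usable.sum() < 2:
        raise DegenerateDegreeDistribution("degenerate degree distribution")
    x = np.log10(mean_k[usable])
    y = np.log10(counts[usable] / k.size)
    res = stats.linregress(x, y)
    fit = float(res.rvalue**2 * (1.0 if res.slope < 0 else -1.0 if res.slope > 0 else 0.0))
    return ScaleFreeFit(power=power, fit_index=fit, slope=float(res.slope))


@dataclass(frozen=True)
class SoftThresholdResult:
    beta: int
    fits: pd.DataFrame  # columns: power, fit_index, slope, mean_k
    reached_cut: bool


def _default_signed_power(n_samples: int) -> int:
    """Fallback soft power for signed networks by sample count.

    The usual practice when no power reaches the scale-free fit cut
    (common when the data are dominated by a few large co-expression
    groups, whose connectivity distribution is not scale-free): fewer
    samples need a larger power to suppress spurious correlations.
    """
    if n_samples < 20:
        return 18
    if n_samples < 30:
        return 16
    if n_samples < 40:
        return 14
    return 12


def pick_soft_threshold(logmat: pd.DataFrame,
                        powers: list[int] | range = range(1, 26),
                        fit_cut: float = 0.8,
                        n_bins: int = 10) -> SoftThresholdResult:
    """Choose the smallest soft power whose scale-free fit reaches ``fit_cut``.

    Evaluates every candidate power and returns the full per-power table
    so the choice is auditable.  When no power reaches the cut, the
    sample-count-based default power for signed networks is returned
    (the closest available candidate) with ``reached_cut=False``;
    chasing the maximal fit index instead would select ever-larger
    powers on data whose degree distribution is simply not scale-free.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending list")
    cor = correlation_matrix(logmat)
    half = (1.0 + cor.to_numpy()) / 2.0
    np.fill_diagonal(half, 0.0)  # self term excluded from connectivity
    rows = []
    for p in powers:
        k = (half**p).sum(axis=1)
        try:
            fit = scale_free_fit(k, n_bins=n_bins, power=p)
            rows.append((p, fit.fit_index, fit.slope, float(k.mean())))
        except DegenerateDegreeDistribution:
            rows.append((p, np.nan, np.nan, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit_index", "slope", "mean_k"])
    ok = table[table["fit_index"] >= fit_cut]
    if len(ok):
        return SoftThresholdResult(int(ok["power"].iloc[0]), table, True)
    if table["fit_index"].isna().all():
        raise DegenerateDegreeDistribution("no power produced a usable fit")
    want = _default_signed_power(logmat.shape[1])
    best = min(powers, key=lambda p: (abs(p - want), p))
    return SoftThresholdResult(int(best), table, False)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    L_ij = sum_u a_iu * a_uj over u distinct from i and j, and
    k_i = sum_{u != i} a_iu.  Shared neighbours raise the overlap above
    the direct edge weight alone.  Diagonal set to 1.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency values must lie in [0, 1]")
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def diss_tom(tom: pd.DataFrame) -> pd.DataFrame:
    """Element-wise 1 - TOM; zero diagonal. The clustering dissimilarity."""
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=tom.index, columns=tom.columns)


def connectivity(adj: pd.DataFrame,
                 assignment: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene weighted connectivity, optionally split by module.

    Whole-network k_i sums the gene's adjacency to every other gene;
    intramodular kIM_i sums only edges to genes sharing its module label
    (returned as column ``kIM`` when an assignment is given; genes in a
    singleton module get kIM 0).
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    out = pd.DataFrame({"k": a.sum(axis=1)}, index=adj.index)
    if assignment is not None:
        assignment = assignment.reindex(adj.index)
        if assignment.isna().any():
            missing = assignment.index[assignment.isna()]
            raise ValueError(f"assignment missing gene(s): {list(missing[:5])}")
        labels = assignment.to_numpy()
        same = labels[:, None] == labels[None, :]
        out["kIM"] = (a * same).sum(axis=1)
        out["module"] = labels
    return out


def scaled_intramodular_degree(kim: pd.Series, assignment: pd.Series) -> pd.Series:
    """Scale intramodular connectivity to [0, 1] by the module maximum.

    The best-connected gene of each module scores exactly 1 ("scaled
    degree").  A module whose maximal kIM is 0 scores all members 0.
    Grey (unassigned) genes are scaled within grey for completeness but
    carry no hub meaning.
    """
    kim = kim.astype(float)
    out = pd.Series(0.0, index=kim.index, name="scaled_degree")
    for label, members in assignment.groupby(assignment).groups.items():
        vals = kim.loc[members]
        top = vals.max()
        if top > 0:
            out.loc[members] = vals / top
    return out
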