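"""Module detection on the TOM dissimilarity.

Average-linkage hierarchical clustering of the dissTOM, a top-down
adaptive branch decomposition of the dendrogram ("tree" style dynamic
cut) with a minimum module size, module eigengenes (first principal
component of the standardized member expression), and greedy merging of
modules whose eigengenes are strongly correlated.

Module labels are size-ranked: ``M1`` is the largest module, and the
reserved label ``grey`` collects genes assigned to no module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .network import GREY


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge history over a fixed leaf (gene) order."""
    linkage: np.ndarray          # scipy (n-1) x 4 merge table
    genes: pd.Index

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(diss: pd.DataFrame) -> Dendrogram:
    """Average-linkage dendrogram of a symmetric dissimilarity matrix."""
    d = diss.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity diagonal must be zero")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, genes=diss.index)


def _size_ranked_labels(groups: list[list[int]], genes: pd.Index,
                        grey_leaves: list[int]) -> pd.Series:
    order = sorted(range(len(groups)),
                   key=lambda g: (-len(groups[g]), min(groups[g])))
    labels = pd.Series(GREY, index=genes, name="module", dtype=object)
    for rank, g in enumerate(order, start=1):
        labels.iloc[groups[g]] = f"M{rank}"
    labels.iloc[grey_leaves] = GREY
    return labels


def _subtree_heights(node) -> list[float]:
    """Merge heights of all internal nodes of a subtree."""
    out, stack = [], [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            out.append(nd.dist)
            stack.extend((nd.left, nd.right))
    return out


def _cut_subtree(node, level: float) -> list:
    """Maximal subtrees of ``node`` whose join height is below ``level``."""
    parts, stack = [], [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist < level:
            parts.append(nd)
        else:
            stack.extend((nd.left, nd.right))
    return parts


def dynamic_tree_cut(dendro: Dendrogram, min_module_size: int = 30,
                     cut_height_fraction: float = 0.99,
                     branch_split_gap: float = 0.05) -> pd.Series:
    """Adaptive top-down branch decomposition of the dendrogram.

    The tree is first cut at ``cut_height_fraction`` times the maximal
    merge height.  Each resulting branch is decomposed recursively from
    its internal height structure: a gap in the branch's sorted merge
    heights marks a sub-branch boundary when it exceeds
    ``branch_split_gap`` times the dendrogram height range (the
    branch-sensitivity default); the branch is re-cut inside the
    highest such gap — separating its loose top-level joins from the
    cohesive structure underneath — and the pieces decomposed in turn.
    A cut that would leave no module-sized piece is rejected and the
    branch kept whole.  A branch with no significant internal gap is
    cohesive and accepted as a module when it has at least
    ``min_module_size`` leaves; every remaining leaf — loosely chained
    singletons and sub-threshold fragments — is labeled grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = dendro.genes
    n = len(genes)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; everything is grey")
        return pd.Series(GREY, index=genes, name="module", dtype=object)

    root = to_tree(dendro.linkage)
    h = dendro.heights
    hmax, hmin = float(h.max()), float(h.min())
    gap_abs = branch_split_gap * max(hmax - hmin, np.finfo(float).tiny)
    cut_h = cut_height_fraction * hmax

    groups: list[list[int]] = []
    grey_leaves: list[int] = []

    def accept(node) -> None:
        leaves = node.pre_order(lambda nd: nd.id)
        if len(leaves) >= min_module_size:
            groups.append(leaves)
        else:
            grey_leaves.extend(leaves)

    # forest of maximal subtrees joining at or below the static cut
    stack = [part for part in _cut_subtree(root, cut_h * (1 + 1e-12))]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            grey_leaves.append(node.id)
            continue
        heights = sorted(_subtree_heights(node))
        gaps = np.diff(heights)
        significant = np.flatnonzero(gaps >= gap_abs)
        if len(significant) == 0:
            accept(node)
            continue
        # re-cut inside the highest significant internal gap
        split_at = int(significant[-1])
        level = (heights[split_at] + heights[split_at + 1]) / 2.0
        pieces = _cut_subtree(node, level)
        if max(p.count for p in pieces) < min_module_size <= node.count:
            accept(node)  # the gap separates no module core; keep whole
        else:
            stack.extend(pieces)

    return _size_ranked_labels(groups, genes, grey_leaves)


@dataclass(frozen=True)
class Eigengene:
    """Module summary profile: first PC of the standardized member rows."""
    module: str
    scores: pd.Series            # per-sample, unit norm
    variance_explained: float


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("module contains constant expression row(s)")
    return (x - mu) / sd


def module_eigengene(logmat: pd.DataFrame, members: pd.Index | list,
                     label: str = "") -> Eigengene:
    """First principal component of a module's standardized expression.

    The score vector has unit norm and is oriented to correlate
    non-negatively with the members' mean standardized profile; if that
    correlation is exactly zero the first sample's score is made
    non-negative.  ``variance_explained`` is the share of total variance
    carried by the first component.
    """
    sub = logmat.loc[list(members)]
    if sub.shape[0] < 1 or sub.shape[1] < 2:
        raise ValueError("eigengene needs >= 1 member and >= 2 samples")
    x = _standardize_rows(sub.to_numpy(dtype=float))
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = vt[0]
    total = float((s**2).sum())
    var = float(s[0] ** 2 / total) if total > 0 else 0.0
    mean_profile = x.mean(axis=0)
    orient = float(eig @ mean_profile)
    if orient < 0 or (orient == 0 and eig[0] < 0):
        eig = -eig
    return Eigengene(module=label,
                     scores=pd.Series(eig, index=logmat.columns, name=label),
                     variance_explained=var)


def eigengene_matrix(logmat: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Eigengene score vectors for every non-grey module (samples x modules)."""
    cols = {}
    for label in sorted(assignment.unique()):
        if label == GREY:
            continue
        members = assignment.index[assignment == label]
        cols[label] = module_eigengene(logmat, members, label).scores
    return pd.DataFrame(cols)


def merge_modules(logmat: pd.DataFrame, assignment: pd.Series,
                  cor_threshold: float = 0.85) -> pd.Series:
    """Greedily merge module pairs whose eigengenes correlate >= threshold.

    After each merge all eigengenes are recomputed and the currently
    most-correlated qualifying pair is merged next; grey never merges.
    Ties are broken toward the smaller combined module, then
    lexicographically.  On return no remaining pair of non-grey
    eigengenes reaches the threshold, and labels are re-ranked by size.
    """
    assignment = assignment.copy()
    while True:
        labels = sorted(set(assignment.unique()) - {GREY})
        if len(labels) < 2:
            break
        eigs = eigengene_matrix(logmat, assignment)
        cor = np.corrcoef(eigs.to_numpy().T)
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                r = cor[i, j]
                if r < cor_threshold:
                    continue
                combined = int((assignment == labels[i]).sum()
                               + (assignment == labels[j]).sum())
                key = (-r, combined, labels[i], labels[j])
                if best is None or key < best[0]:
                    best = (key, labels[i], labels[j])
        if best is None:
            break
        _, a, b = best
        assignment[assignment == b] = a
    # re-rank labels by final module size
    sizes = assignment[assignment != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rename = {old: f"M{rank}" for rank, old in enumerate(order, start=1)}
    # two-step rename avoids label collisions between old and new names
    tmp = assignment.map(lambda m: m if m == GREY else f"_{m}")
    return tmp.map(lambda m: GREY if m == GREY else rename[m[1:]]).rename("module")
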