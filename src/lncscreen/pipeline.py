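"""End-to-end composition of the two screens.

``run_essential_screen`` chains expression filtering, biotype
restriction, log transform, soft-power selection, signed adjacency,
TOM, average-linkage clustering, dynamic tree cut, eigengene merging
and intramodular-degree essentiality ranking.  ``run_candidate_screen``
intersects essential lncRNAs with differentially expressed lncRNAs;
``run_regulator_screen`` correlates candidate regulators with a target
over a time course.  All parameters live in :class:`PipelineConfig`,
whose defaults are the screen's published operating point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .de import load_de_results
from .expression import filter_expressed, log_transform, restrict_biotypes
from .modules import dynamic_tree_cut, eigengene_matrix, hierarchical_cluster, \
    merge_modules
from .network import GREY, SoftThresholdResult, connectivity, diss_tom, \
    pick_soft_threshold, scaled_intramodular_degree, signed_adjacency, \
    topological_overlap
from .regulators import classify_regulators, correlate_with_target
from .screen import essential_genes, overlap_candidates

log = logging.getLogger("lncscreen")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable screen parameters with their standard defaults.

    Defaults: detection floor FPKM 0.1 in >= 25% of samples; soft powers
    1..25 with scale-free fit cut 0.8; minimum module size 30; eigengene
    merge correlation 0.85; essential top fraction 0.25; DE adjusted-p
    0.05; strong-correlation cuts +/-0.95; log base 2.
    """
    min_value: float = 0.1
    min_fraction: float = 0.25
    log_base: float = 2.0
    powers: tuple[int, ...] = tuple(range(1, 26))
    fit_cut: float = 0.8
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    branch_split_gap: float = 0.05
    merge_cor: float = 0.85
    top_fraction: float = 0.25
    adj_p_threshold: float = 0.05
    pos_cut: float = 0.95
    neg_cut: float = -0.95
    seed: int = 0

    def config_hash(self) -> str:
        text = ";".join(f"{f.name}={getattr(self, f.name)}"
                        for f in dataclasses.fields(self))
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` text config; unknown keys error."""
        kwargs = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in names:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                if key == "powers":
                    kwargs[key] = tuple(int(v) for v in value.split(","))
                elif key in ("min_module_size", "seed"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)

    def header_lines(self) -> list[str]:
        return [f"lncscreen {__version__}",
                f"config_hash {self.config_hash()}",
                f"seed {self.seed}"]


@dataclass
class EssentialScreenResult:
    expressed_mask: pd.Series
    logmat: pd.DataFrame
    soft: SoftThresholdResult
    assignment: pd.Series
    connectivity: pd.DataFrame     # columns k, kIM, module, scaled_degree
    essential: pd.DataFrame
    eigengenes: pd.DataFrame

    @property
    def module_summary(self) -> pd.DataFrame:
        sizes = self.assignment.value_counts()
        ess = self.essential["module"].value_counts()
        out = pd.DataFrame({"size": sizes,
                            "n_essential": ess.reindex(sizes.index, fill_value=0)})
        out.index.name = "module"
        return out.sort_values("size", ascending=False)


def run_essential_screen(matrix: pd.DataFrame, annotation: pd.DataFrame,
                         config: PipelineConfig = PipelineConfig(),
                         ) -> EssentialScreenResult:
    """Expression matrix + annotation -> ranked essential genes.

    Stages: detection filter, lncRNA/mRNA restriction, log transform,
    soft-power pick, signed adjacency, TOM/dissTOM, average-linkage
    dendrogram, dynamic tree cut, eigengene merge, connectivity and
    top-quartile essentiality call.  Deterministic for fixed inputs.
    """
    log.info("filtering: FPKM >= %g in >= %g of samples",
             config.min_value, config.min_fraction)
    kept, mask = filter_expressed(matrix, config.min_value, config.min_fraction)
    kept = restrict_biotypes(kept, annotation)
    log.info("%d of %d genes expressed after biotype restriction",
             kept.shape[0], matrix.shape[0])
    logmat = log_transform(kept, base=config.log_base)

    soft = pick_soft_threshold(logmat, list(config.powers), config.fit_cut)
    if not soft.reached_cut:
        log.warning("no soft power reached fit cut %.2f; "
                    "using signed-network default power %d",
                    config.fit_cut, soft.beta)
    log.info("soft power %d (scale-free fit reached: %s)",
             soft.beta, soft.reached_cut)

    from .network import correlation_matrix
    adj = signed_adjacency(correlation_matrix(logmat), soft.beta)
    diss = diss_tom(topological_overlap(adj))
    dendro = hierarchical_cluster(diss)
    assignment = dynamic_tree_cut(
        dendro, min_module_size=config.min_module_size,
        cut_height_fraction=config.cut_height_fraction,
        branch_split_gap=config.branch_split_gap)
    assignment = merge_modules(logmat, assignment, cor_threshold=config.merge_cor)
    n_mod = assignment.nunique() - int((assignment == GREY).any())
    log.info("%d modules, %d grey genes", n_mod, int((assignment == GREY).sum()))

    conn = connectivity(adj, assignment)
    conn["scaled_degree"] = scaled_intramodular_degree(conn["kIM"], assignment)
    essential = essential_genes(assignment, conn["kIM"], conn["scaled_degree"],
                                top_fraction=config.top_fraction)
    eigs = (eigengene_matrix(logmat, assignment)
            if (assignment != GREY).any() else pd.DataFrame(index=logmat.columns))
    return EssentialScreenResult(expressed_mask=mask, logmat=logmat, soft=soft,
                                 assignment=assignment, connectivity=conn,
                                 essential=essential, eigengenes=eigs)


def run_candidate_screen(result: EssentialScreenResult,
                         annotation: pd.DataFrame,
                         de_table: pd.DataFrame,
                         config: PipelineConfig = PipelineConfig(),
                         ) -> pd.DataFrame:
    """Essential lncRNAs x significant DE lncRNAs -> candidate table.

    ``de_table`` is the output of :func:`lncscreen.de.load_de_results`
    or :func:`lncscreen.de.simple_de_test`; only lncRNA rows significant
    at the configured adjusted-p threshold enter the overlap.
    """
    if len(de_table) and not len(result.logmat.index.intersection(de_table.index)):
        raise ValueError("DE table and screen share no gene ids")
    lnc = annotation["biotype"] == "lncRNA"
    essential_lnc = result.essential.loc[
        result.essential.index.intersection(annotation.index[lnc])]
    sig = de_table[(de_table["adj_p"] <= config.adj_p_threshold)
                   & de_table.index.isin(annotation.index[lnc])]
    return overlap_candidates(essential_lnc, sig, annotation)


def run_regulator_screen(timecourse: pd.DataFrame, target: str,
                         candidates: list[str],
                         config: PipelineConfig = PipelineConfig(),
                         ) -> pd.DataFrame:
    """Correlation screen of candidate regulators against a target profile."""
    records = correlate_with_target(timecourse, target, candidates)
    return classify_regulators(records, pos_cut=config.pos_cut,
                               neg_cut=config.neg_cut)


def write_report(table: pd.DataFrame, path: str | Path,
                 config: PipelineConfig) -> None:
    """Write a result table as TSV with a provenance comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in config.header_lines():
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", float_format="%.10g")
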