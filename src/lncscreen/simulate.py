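"""Synthetic transcriptome generators with known ground truth.

Three generators emulate the statistical structure the screen assumes:

* a gene x sample FPKM matrix with planted co-expression modules — each
  module has a shared per-sample profile, per-gene loadings with a
  designated maximal-loading hub, Gaussian noise on the log2 scale and a
  back-transform 2^x - 1 so FPKM-level filter semantics stay meaningful
  — plus an unassignable remainder of independent noise genes and a
  biotype mixture with a stated lncRNA fraction;
* a two-condition differential-expression pair with stated log2 effects;
* a short time course in which designated regulator profiles achieve
  requested Pearson correlations with a target profile *exactly*, by an
  orthogonalized construction rather than sampling.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX",)

TRUTH_UNASSIGNED = "none"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: gene count, loading range and hub count.

    ``hub_loading`` defaults to the loading-range maximum; it can be
    raised to plant a hub that stands clear of the ordinary members.
    """
    size: int
    loading_range: tuple[float, float] = (0.6, 0.9)
    n_hubs: int = 1
    hub_loading: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the planted-module benchmark.

    Five modules spanning sizes 30-120, 20 samples, log2-scale noise sd
    0.5 and a ~19% lncRNA biotype fraction (the share of lncRNAs among
    expressed lncRNA+mRNA genes in bulk myeloid data); hubs are planted
    as lncRNAs so the end-to-end candidate screen has known positives.
    """
    seed: int
    n_samples: int = 20
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(120), ModuleSpec(90), ModuleSpec(70),
        ModuleSpec(50), ModuleSpec(30),
    )
    n_noise_genes: int = 40
    lncrna_fraction: float = 0.19
    other_fraction: float = 0.0
    noise_sd: float = 0.5
    hub_noise_factor: float = 0.25
    baseline_range: tuple[float, float] = (2.0, 6.0)
    hub_biotype: str | None = "lncRNA"

    def __post_init__(self):
        for m in self.modules:
            if m.size < 1:
                raise ValueError("module size must be >= 1")
            if m.n_hubs > m.size:
                raise ValueError("hub count cannot exceed module size")
            lo, hi = m.loading_range
            if not (0 < lo <= hi <= 1):
                raise ValueError("loading range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.lncrna_fraction + self.other_fraction <= 1:
            raise ValueError("biotype fractions must sum within [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure emitted alongside a simulated matrix."""
    module: pd.Series          # gene -> planted module label or "none"
    biotype: pd.Series
    hubs: tuple[str, ...]
    loadings: pd.Series        # NaN for noise genes
    de_genes: tuple[str, ...] = ()
    de_effect: float = 0.0
    regulator_correlations: dict = field(default_factory=dict)


def simulate_modular_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an FPKM matrix with planted co-expression modules.

    Gene g of module m has log2 expression b_g + lambda_g * e_m + eps
    with e_m the module's shared sample profile, lambda_g the gene
    loading (hubs sit at the range maximum), b_g a per-gene baseline
    and eps ~ Normal(0, noise_sd).  Hubs are additionally low-noise
    (``hub_noise_factor`` x noise_sd): a planted hub must actually be
    the kind of tightly-coupled gene whose intramodular connectivity
    ranks at the top, otherwise the emitted ground truth would not be
    true of the emitted matrix.  Noise genes get independent unit-sd
    profiles.  FPKM = max(2^x - 1, 0).

    Returns (matrix, annotation, truth); deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_total = sum(m.size for m in config.modules) + config.n_noise_genes
    genes = [f"GENE{i:05d}" for i in range(n_total)]
    samples = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    if len(config.modules) >= config.n_samples:
        raise ValueError("need fewer modules than samples for distinct profiles")

    # Module profiles are mutually orthogonal with zero mean and unit
    # sample variance, so planted modules are uncorrelated by
    # construction rather than approximately so.
    g = rng.standard_normal((config.n_samples, len(config.modules)))
    g -= g.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(g)
    profiles = q * np.sqrt(config.n_samples)

    log2x = np.empty((n_total, config.n_samples))
    truth_module = pd.Series(TRUTH_UNASSIGNED, index=pd.Index(genes, name="gene_id"),
                             dtype=object, name="planted_module")
    loadings = pd.Series(np.nan, index=truth_module.index, name="loading")
    baselines = rng.uniform(*config.baseline_range, size=n_total)
    hubs: list[str] = []

    row = 0
    for mi, spec in enumerate(config.modules, start=1):
        profile = profiles[:, mi - 1]
        lam = rng.uniform(*spec.loading_range, size=spec.size)
        lam[: spec.n_hubs] = (spec.hub_loading if spec.hub_loading is not None
                              else spec.loading_range[1])
        block = genes[row: row + spec.size]
        hubs.extend(block[: spec.n_hubs])
        eps_sd = np.full(spec.size, config.noise_sd)
        eps_sd[: spec.n_hubs] *= config.hub_noise_factor
        eps = rng.normal(0.0, 1.0, size=(spec.size, config.n_samples)) \
            * eps_sd[:, None]
        log2x[row: row + spec.size] = (
            baselines[row: row + spec.size, None] + lam[:, None] * profile + eps
        )
        truth_module.iloc[row: row + spec.size] = f"P{mi}"
        loadings.iloc[row: row + spec.size] = lam
        row += spec.size
    if config.n_noise_genes:
        log2x[row:] = baselines[row:, None] + rng.standard_normal(
            (config.n_noise_genes, config.n_samples)
        )

    matrix = pd.DataFrame(np.maximum(2.0 ** log2x - 1.0, 0.0),
                          index=truth_module.index, columns=samples)

    draw = rng.random(n_total)
    biotype = np.where(draw < config.lncrna_fraction, "lncRNA",
                       np.where(draw < config.lncrna_fraction + config.other_fraction,
                                "other", "mRNA"))
    biotype = pd.Series(biotype, index=truth_module.index, name="biotype")
    if config.hub_biotype is not None:
        biotype.loc[hubs] = config.hub_biotype
    annotation = pd.DataFrame({
        "symbol": [f"Sym{i}" for i in range(n_total)],
        "biotype": biotype,
        "chromosome": rng.choice(CHROMOSOMES, size=n_total),
    }, index=truth_module.index)

    truth = GroundTruth(module=truth_module, biotype=biotype,
                        hubs=tuple(hubs), loadings=loadings)
    return matrix, annotation, truth


def simulate_de(matrix: pd.DataFrame, de_genes, log2_effect: float,
                noise_sd: float, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive condition B from condition A by a planted log2 shift.

    B's log2(FPKM + 1) equals A's plus ``log2_effect`` for the planted
    genes plus fresh Normal(0, noise_sd) noise everywhere; both
    conditions share the sample grid.  Deterministic given the seed.
    """
    de_genes = list(de_genes)
    missing = set(de_genes) - set(matrix.index)
    if missing:
        raise ValueError(f"DE gene(s) absent from matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    log_a = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    shift = np.zeros((matrix.shape[0], 1))
    shift[[matrix.index.get_loc(g) for g in de_genes]] = log2_effect
    log_b = log_a + shift + rng.normal(0.0, noise_sd, size=log_a.shape)
    b = pd.DataFrame(np.maximum(2.0 ** log_b - 1.0, 0.0),
                     index=matrix.index, columns=matrix.columns)
    return matrix.copy(), b


def simulate_de_experiment(n_genes: int, n_per_group: int, de_genes: int,
                           log2_effect: float, noise_sd: float, seed: int,
                           baseline_range: tuple[float, float] = (3.0, 7.0),
                           ) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Flat two-condition experiment for testing the built-in DE caller.

    Every gene is log2-normal around its baseline with sd ``noise_sd``;
    the first ``de_genes`` genes carry ``log2_effect`` in group B.
    Returns (matrix over both groups, sample -> group map, planted ids).
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"GENE{i:05d}" for i in range(n_genes)], name="gene_id")
    samples = [f"A{j:02d}" for j in range(n_per_group)] + \
              [f"B{j:02d}" for j in range(n_per_group)]
    base = rng.uniform(*baseline_range, size=n_genes)
    log2x = base[:, None] + rng.normal(0.0, noise_sd,
                                       size=(n_genes, 2 * n_per_group))
    log2x[:de_genes, n_per_group:] += log2_effect
    matrix = pd.DataFrame(np.maximum(2.0 ** log2x - 1.0, 0.0),
                          index=genes, columns=samples)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    return matrix, groups, genes[:de_genes]


@dataclass(frozen=True)
class TimecourseSpec:
    """Requested time-course structure: the target profile and the exact
    Pearson correlation each regulator should realize with it."""
    time_points: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0, 48.0, 72.0)
    target: str = "TARGET"
    regulator_correlations: dict[str, float] = field(default_factory=dict)
    mean: float = 10.0
    scale: float = 2.0


def simulate_timecourse(spec: TimecourseSpec,
                        seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Construct a time course whose correlations with the target are exact.

    The target profile z is drawn once and standardized; a regulator at
    requested correlation rho is built as rho * z + sqrt(1 - rho^2) * w
    with w a standardized residual orthogonal to z, so the realized
    Pearson correlation equals rho to machine precision.
    """
    t = np.asarray(spec.time_points, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("time points must be strictly increasing")
    for g, rho in spec.regulator_correlations.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation for {g!r} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    n = t.size

    def _unit_centered(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.linalg.norm(v)

    z = _unit_centered(rng.standard_normal(n))
    rows = {spec.target: spec.mean + spec.scale * z}
    for g, rho in spec.regulator_correlations.items():
        w = rng.standard_normal(n)
        w = w - w.mean() - (w @ z) * z          # center and remove z component
        while np.linalg.norm(w) < 1e-9:         # pragma: no cover - measure zero
            w = rng.standard_normal(n)
            w = w - w.mean() - (w @ z) * z
        w /= np.linalg.norm(w)
        rows[g] = spec.mean + spec.scale * (rho * z + np.sqrt(1.0 - rho**2) * w)
    tc = pd.DataFrame(rows, index=[f"{h:g}" for h in t]).T
    tc.index.name = "gene_id"
    truth = GroundTruth(
        module=pd.Series(dtype=object), biotype=pd.Series(dtype=object),
        hubs=(), loadings=pd.Series(dtype=float),
        regulator_correlations=dict(spec.regulator_correlations),
    )
    return tc, truth
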