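# Methods

This note documents the models, parameter choices and numerical
conventions behind `lncscreen`, and what the synthetic benchmarks do
and do not demonstrate.

## Expression preprocessing

Input is a genes × samples FPKM matrix (nonnegative, finite; duplicate
gene or sample identifiers are a hard error, never silently
aggregated). A gene counts as *expressed* when FPKM ≥ `min_value` in at
least `min_fraction` of samples; both comparisons are inclusive, so a
gene at exactly the floor in exactly the required share of samples is
kept. Defaults are 0.1 and 25%, the conventional detection floor for
bulk FPKM data. The screen then restricts to lncRNA and mRNA biotypes
(GENCODE `gene_type` values are collapsed by a documented mapping:
`protein_coding` → mRNA, the long non-coding classes → lncRNA,
everything else → other) and transforms to log(FPKM + 1).

The logarithm base is a convention, not a model choice: changing base
rescales every value by one positive constant, so correlations —
and therefore adjacency, TOM, modules and all downstream results — are
identical for base 2 versus natural log (asserted to 1e-10 in the test
suite). The default is base 2.

## Signed network and soft-threshold selection

The co-expression network is *signed*: adjacency
`a_ij = ((1 + cor_ij)/2)^β` maps positive correlation toward 1 and
negative toward 0, so anticorrelated genes do not end up in the same
module. Diagonals of adjacency and TOM are fixed at 1 for reporting;
every connectivity sum excludes the self term.

β is selected by the scale-free topology criterion: for each candidate
power (default 1…25) the whole-network connectivity vector is binned
into 10 equal-width bins and log10(relative frequency) is regressed on
log10(mean connectivity) over usable bins; the fit index is the signed
R² (positive when the slope is negative, i.e. when the degree
distribution decreases). The selected β is the smallest power with fit
index ≥ 0.8. The per-power table is always returned so the choice is
auditable; bin count is configurable.

**Fallback.** When no power reaches the cut — the situation whenever
the data are dominated by a few large co-expression groups, whose
connectivity distribution is bimodal rather than scale-free — the
package uses the standard sample-count default for signed networks
(18 / 16 / 14 / 12 for < 20 / < 30 / < 40 / ≥ 40 samples, nearest
available candidate), with a warning flag on the result. An
alternative fallback, the power with the maximal fit index, was
evaluated and rejected: on modular data the fit index creeps upward
monotonically with power, so that rule degenerates into "use the
largest candidate power", where adjacency and TOM values collapse
toward 0 and small modules fragment at the clustering stage. On the
default benchmark the max-fit rule lost the smallest planted module to
grey in ~4/10 seeds; the sample-size default loses none.

## Topological overlap and module detection

`TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`L_ij = Σ_{u≠i,j} a_iu a_uj`: two genes overlap strongly when they are
directly connected *and* share neighbours. The implementation is
vectorized and is checked against a literal triple-loop evaluation to
1e-12 on a thousand random 5–10-gene networks. Clustering runs on
`dissTOM = 1 − TOM` with average linkage.

**Dynamic tree cut (tree variant).** The dendrogram is first cut at
`cut_height_fraction` (default 0.99) of the maximal merge height. Each
resulting branch is decomposed top-down from its internal height
structure: the branch's merge heights are sorted, and any gap
exceeding `branch_split_gap` (default 0.05) × the dendrogram height
range marks a sub-branch boundary; the branch is re-cut inside the
highest such gap — separating loosely chained top-level joins from the
cohesive structure underneath — and the pieces are decomposed
recursively. A cut that would leave no piece of at least
`min_module_size` leaves is rejected and the branch kept whole.
Cohesive branches with ≥ `min_module_size` (default 30) leaves become
modules; all remaining leaves are *grey*. The highest-gap rule (rather
than largest-gap) is deliberate: the largest internal gap of a branch
can sit near its bottom, and cutting there shatters the branch into
singletons. No PAM-like reassignment stage is implemented; grey genes
stay grey.

**Eigengenes and merging.** A module eigengene is the first principal
component (unit-norm sample scores) of the module's per-gene
standardized expression, oriented to correlate non-negatively with the
members' mean standardized profile; when that correlation is exactly
zero (e.g. a two-gene module of mutually negated profiles) the first
sample's score is made non-negative. Modules whose eigengenes
correlate at or above `merge_cor` (default 0.85) are merged greedily,
highest correlation first, recomputing after every merge; ties break
toward the smaller combined module, then lexicographically. On return
no remaining pair reaches the threshold (asserted on every benchmark
run). Final labels are size-ranked M1 (largest) … Mk, plus grey.

## Essentiality and the candidate screen

Within each non-grey module, genes are ranked by intramodular
connectivity `kIM` (sum of adjacency to same-module genes) and the top
25% — realized as ⌈0.25 × size⌉, ties broken by scaled degree then
gene id — are called *essential*. Grey is ineligible: it is a
catch-all, not a module. Scaled degree divides `kIM` by the module
maximum, so each module's best-connected gene scores exactly 1.
Essential lncRNAs intersected with differentially expressed lncRNAs
(adjusted p ≤ 0.05, inclusive) give the candidate table, sorted by
adjusted p. Enrichment of candidate sets in annotation terms uses the
one-sided (over-representation) Fisher exact test with optional
Benjamini–Hochberg adjustment; term lists are caller-supplied.

## Differential expression

Real analyses consume result tables from dedicated DE tools; the
loader only applies the significance contract and derives direction
from the effect sign. The built-in caller (Welch two-sample t on
log2(FPKM + 1), BH adjustment) exists so fully synthetic runs need no
external tool and is labeled as such in its output metadata. Its
operating characteristics under the generator's conditions: raw-p
type-I rate 5% ± 2% on 2000 null genes, sensitivity ≥ 0.9 for 4-fold
effects at noise sd 0.3 with 10 + 10 samples.

## Regulator screen

Candidate regulators are correlated with a target across a time course
(≥ 3 strictly increasing time points; n is always taken from the data,
never hard-coded). Significance uses the exact t-distribution
(regularized incomplete beta), not a normal approximation — with n = 6
the two-sided p has the closed form `1 − (3/2)|r| + (1/2)|r|³`, which
the t-CDF path matches to 1e-12 and which reproduces published 6-point
correlation p-values to three significant figures wherever the printed
r rounds stably. Classification cuts (±0.95) are inclusive.
Correlations are computed on the values as provided; the loader does
not log-transform time courses.

## qPCR quantification

Comparative-Ct arithmetic with amplification efficiency fixed at 2 (no
efficiency correction, standard curves or melt QC): fold change
2^−ΔΔCt against a reference gene and calibrator sample, relative
expression 2^−ΔCt, replicate summaries as mean ± SEM (sd/√n, sample
sd) with a two-tailed t-test — Welch by default, pooled by flag, since
equal variances are rarely defensible for triplicate Cts — and star
tiers at inclusive boundaries 0.05/0.01/0.001.

## Synthetic data: what it emulates, and what it does not

`simulate_modular_expression` plants K modules: module m has a shared
sample profile `e_m`, and gene g in m gets log2 expression
`b_g + λ_g e_m + ε`, with baseline `b_g ~ U(2, 6)`, loading `λ_g` drawn
from the module's range, and `ε ~ N(0, noise_sd)`; the matrix is
back-transformed by `2^x − 1` (clipped at 0) so FPKM-level filter
semantics stay meaningful. Unassignable "noise" genes get independent
unit-sd profiles. Biotypes are assigned at a configurable lncRNA
fraction (default 0.19, the typical lncRNA share among expressed
lncRNA + mRNA genes in bulk myeloid data).

Two generator choices ensure the emitted ground truth is *true of the
emitted matrix*:

- **Orthogonal module profiles.** Profiles are drawn as orthogonalized,
  zero-mean, unit-variance vectors (QR of centered Gaussians), so
  planted modules are uncorrelated by construction. With i.i.d.
  profiles at 20 samples, two "distinct" modules can correlate ~0.6 by
  chance, making their planted separation false.
- **Low-noise hubs.** Hubs sit at the loading-range maximum *and* get
  residual noise scaled by `hub_noise_factor` (default 0.25). Loading
  alone gives no reliable connectivity margin at realistic noise —
  sampling error on realized correlations is worth ~±0.11 of loading
  at 20 samples, and a "hub" drawn from the same range as its
  neighbours lands outside the top quartile of its own module roughly
  a third of the time.

The default benchmark (five modules of 120/90/70/50/30 genes, loadings
0.6–0.9, 20 samples, noise sd 0.5, 40 noise genes) is the package's
standard operating point: across seeds 1–10 the recovered partition
matches the planted one with ARI ≥ 0.92 (ARI computed over all genes,
grey/none as ordinary labels), all five modules and all planted hubs
are recovered, and the end-to-end candidate screen finds every planted
hub lncRNA carrying a planted differential effect.

`simulate_timecourse` constructs regulator profiles as
`ρ·z + √(1−ρ²)·w` with `w` a standardized residual orthogonal to the
standardized target `z`, so requested correlations are realized exactly
(to machine precision) rather than sampled — regulator-screen tests
are therefore deterministic. `simulate_de` derives condition B from A
by a planted log2 shift plus fresh noise; `simulate_de_experiment`
provides the flat two-group design used for caller calibration. All
generators are pure functions of (config, seed).

**Limitations.** The generator produces Gaussian log-scale noise with
a single shared profile per module; it does not imitate count-level
sequencing noise (negative binomial reads), library-size artifacts,
batch structure, overlapping/nested modules, or correlated noise
between genes. Passing the benchmark therefore shows the pipeline
recovers clean planted structure at moderate noise — not that it is
robust to every pathology of real RNA-seq. Problem sizes in the tests
(hundreds of genes, 10–20 samples) are chosen to exercise every code
path quickly; the dense-matrix implementation itself is intended for
up to ~20,000 genes on one machine.

## Determinism and provenance

Every pipeline stage is a deterministic function of its inputs and
config; report files carry a header with package version, config hash
and seed, and identical (inputs, config) give byte-identical files.
The flat `key = value` config format mirrors `PipelineConfig`, whose
defaults are the screen's standard operating point (FPKM 0.1 / 25%,
powers 1–25, fit cut 0.8, minimum module size 30, merge correlation
0.85, essential top fraction 0.25, adjusted p 0.05, regulator cuts
±0.95).
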