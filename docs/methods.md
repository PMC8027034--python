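# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic-data generator, and the limitations of `modevol`.

## Differential expression

Counts for gene *g*, sample *s* are modeled NB(μ_gs, φ_g) with
`var = μ + φμ²` and `log μ_gs = x_sᵀβ_g + o_s`. The design is cell-means
coded over the three conditions (spruce, pine, SCD) with no intercept, so
contrasts are plain linear combinations of condition means. Offsets o_s are
log effective library sizes: raw library size times a TMM factor (trimmed
mean of M-values against the sample whose upper quartile is closest to the
mean upper quartile; 30% two-sided trim on M, 5% on A,
precision-weighted; factors rescaled to geometric mean 1). The
implementation agrees with edgeR's `calcNormFactors` to 6 significant
digits on test matrices (cross-checked in the suite via Rscript).

GLMs are fitted by IRLS, vectorized across genes sharing one design:
working weights `μ/(1+φμ)`, convergence at max |Δβ| < 1e-8 or 100
iterations, linear predictor clamped to |η| ≤ 50, zero counts floored at
1e-4 during initialization only. Dispersion estimation maximizes the
Cox–Reid adjusted profile likelihood (log-likelihood minus ½ log det XᵀWX)
summed over genes on a 61-point log grid spanning [1e-4, 5], refined by
golden-section search; per-gene MLEs use the same grid with quadratic
interpolation, and tagwise values are the log-scale weighted average of
per-gene MLE and common value with weights residual-df : prior-df
(default prior 10). Contrasts are tested by the likelihood-ratio χ²₁
statistic obtained by re-fitting on the design projected onto the null
space of the contrast. The quasi-likelihood F-test used by edgeR is
deliberately replaced by this LRT: the LRT is fully specified from first
principles and its calibration is verified by simulation in the acceptance
suite (type-I error within the 99% binomial CI of 0.05 and KS distance
< 0.02 at 10⁴ null genes, n = 5 per group, known φ = 0.1).

Genes are tested only if CPM ≥ 1 in ≥ 2 samples (both configurable; the
appropriate filter is data-dependent and deliberately exposed). BH
adjustment is applied per contrast across genes (statsmodels'
implementation, cross-checked against a direct step-up evaluation).

Standardized expression for visualization is regularized log₂-CPM
(`log2((count + c)/(efflib + 2c) × 10⁶)`, prior c = 0.5), the median
within each condition, centered so the three condition values sum to zero.
This replaces a variance-stabilizing rlog transform; the zero-sum centering
is the part downstream consumers rely on and is preserved exactly.

## Module assignment

Significance means BH-FDR < `fdr_alpha` (default 0.05) **and**
log₂FC > `lfc_min` (default 1, log₂ units). A stricter FDR of 0.01 is a
supported alternative and both thresholds are recorded in the run manifest;
0.05 is the default. Wood-type-specific calls additionally require the
spruce-vs-pine contrast to be significant with |log₂FC| > `lfc_min` in the
matching direction, which makes spruce and pine mutually exclusive;
wood-specific labels take precedence over core so reported counts are
disjoint. A gene up on both woods whose between-wood contrast is
significant lands in the module of the larger wood effect (the direction of
the spruce-vs-pine estimate); if the between-wood difference is not
significant it remains core. The core call uses the averaged
(spruce+pine)/2 vs SCD contrast, not the two wood contrasts individually.

## Orthology

Similarity edges require e-value ≤ 1e-5 and percent match ≥ 25 in at least
one direction; weights are maximum bitscores; self-hits are dropped. MCL
runs on the column-stochastic matrix with self-loops at each node's maximum
incident weight (1 for isolated nodes): expansion (matrix square), then
inflation (elementwise power 3, column renormalization), pruning of entries
below 1e-10, until the matrix changes by < 1e-8 (≤ 200 iterations, warning
on non-convergence). Clusters are connected components of the converged
support; singletons are retained. The implementation is exactly equivalent
to an independently coded dense-matrix iteration on random graphs (checked
in the suite) and is invariant to node relabeling and positive weight
scaling. No BLAST-score normalization or inter-species rescaling is
applied; the contract is planted-orthogroup recovery (adjusted Rand ≥ 0.98
on the default synthetic table), not bit-compatibility with OrthoMCL.

Within a cluster, one-to-one representatives are the unique member per
strain, or for duplicated strains the copy with the highest mean bitscore
to the other members (ties by gene id). This replaces gene-tree
reconciliation, which is out of scope; the simplification is recorded in
the run manifest. "Non-trivial" clusters (> 3 sequences and > 1 gene in
some strain) gate duplication-aware summaries.

## Module evolution

Set logic only, no probabilistic ancestral-state model. Conservation at a
branch requires **all** leaves below to carry the module (strict
intersection); tuples missing a member below the branch are skipped rather
than counted as non-conserved. A gain at branch *b* is a conserved tuple
not conserved via the outgroup (some outgroup ortholog outside the module,
or no outgroup member). Gain provenance: `duplicated_at_branch` when the
cluster has ≥ 2 copies in every leaf under *b* and ≤ 1 in each outgroup
leaf; else `recruited_from_X` when all outgroup members share module X;
else `not_induced_in_outgroup` (with a `mixed` annotation for heterogeneous
outgroup states and `absent_in_outgroup` when the outgroup lacks the gene —
genome absence is informative and is reported, not dropped). Losses are
evaluated against observed outgroup induction rather than reconstructed
deeper states; with a single outgroup leaf the two are equivalent. The root
has no outgroup, so gains are not attributed there. Internal nodes are
named deterministically (sorted concatenation of descendant leaf names) so
reports are stable across input rotations.

## Overlap and enrichment

All Fisher tests are one-sided upper hypergeometric tails (every question
asked is an enrichment question); scipy's log-space hypergeometric survival
function is used and agrees with an exact factorial-sum oracle to 1e-12
over all tables with margins ≤ 12. Cross-species overlap uses the universe
of tuples complete in both species, with BH across all cells of all species
pairs as one family; term enrichment treats all terms of one gene-set run
as one family and skips terms with < 3 universe genes. Term hierarchies are
treated flat (no topology-weighted GO algorithm); this is surfaced in the
output metadata.

## Phenotype statistics

`chi2_sf` is the regularized upper incomplete gamma Q(df/2, x/2).
Kruskal–Wallis uses midranks and the tie correction
`1 − Σ(t³−t)/(n³−n)` (on by default, matching R); all-tied input is
degenerate and reported as H = 0, p = 1. The competition test is the plain
χ² goodness-of-fit against equal proportions with df = 1; the Yates
continuity correction is available as a flag but off by default.

## Synthetic data

The generator emulates the study design: four strains on
`(((lacE,lacJ),shas),shim)`, three conditions, five replicates. Module
membership evolves root-to-tip as a state machine; defaults plant core
gains in 5% of the 2000 orthogroups at the root and spruce/pine/core gains
in 5/3/4% at the focal branch (the ancestor of lacE, lacJ, shas), with 2%
losses and 2% duplications there. Gains from a module-bearing state are
recruitments; duplications ride on gains (two copies in every ingroup
leaf) so the duplication provenance category is exercised. The loss
fraction is interpreted as a fraction of all orthogroups, drawn from the
module-bearing groups at the branch.

Counts are NB with per-orthogroup baselines `log₂ mean ~ N(5, 2)`,
dispersions `φ ~ Gamma(2, 0.05)`, and per-sample library sizes uniform on
[0.8, 1.2] × 10⁶ whose ratio to 10⁶ scales the mean
(`μ = libsize/10⁶ × 2^(baseline + effect)`), giving realistic per-sample
totals of a few hundred thousand counts. Planted induction is log₂FC = 2
(core: both woods; spruce/pine: one wood). The similarity table encodes
true clusters as within-cluster hits (bitscore 150–400) plus cross-cluster
noise edges (bitscore 30–60) that pass the e-value and percent-match
filters, so MCL must genuinely separate clusters. The annotation table
plants one term on 80% of focal spruce-gain orthogroups plus 5% background,
among 20 uninformative terms.

Not emulated: sequence-level features (GC/length bias), batch effects,
genome-level gene loss (tuples are complete), unbalanced designs, and
outlier dispersions. Passing recovery tests therefore demonstrates
correctness of the inference chain under the stated generative model, not
robustness to real-data artifacts.

## Problem sizes and numerical choices

The default simulated dataset is 2000 orthogroups (~8100 genes over four
strains, 60 samples), chosen as the package's reference scale for recovery
experiments; calibration studies use 10⁴ null genes and 2000-gene recovery
panels. IRLS tolerance 1e-8; dispersion grid [1e-4, 5] with 61 points;
MCL pruning 1e-10 and convergence 1e-8; Fisher p-values floored at the
smallest positive float. Degenerate inputs (all-zero samples, saturated
designs, empty graphs, zero contrasts, empty competition counts) raise
errors naming the problem rather than returning silent defaults.

## Known limitations

- The DE test is an LRT, slightly liberal at very small n compared to the
  quasi-likelihood F-test; calibration is verified at the design's n = 5.
- One-to-one ortholog choice by bitscore can pick the wrong in-paralog when
  duplicates are nearly equidistant; affected tuples carry duplication
  flags so downstream users can filter.
- Ancestral reconstruction is parsimony-style set logic; it does not model
  assignment uncertainty, so borderline DE calls propagate as hard labels.
- With a single outgroup taxon, losses at the focal branch cannot be
  distinguished from gains in the outgroup lineage; the report states
  outgroup-relative semantics explicitly.
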