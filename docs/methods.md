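# Methods

This note documents the models and procedures bxdnet implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Study design the package assumes

The unit of observation is a strain mean: each row of an expression matrix is
a gene, each column a recombinant-inbred (RI) strain, and the value the
strain's average log2 intensity under one treatment condition. Four
conditions are modelled — saline control (NOS), acute restraint stress (RSS),
acute ethanol (NOE), and restraint followed by ethanol (RSE). Because RI
strains are fixed homozygous mosaics of two parental genomes, genotypes are
coded 0/1 and strain means are genetically replicable observations; no
dominance term is used anywhere.

## Variable-gene selection

Per condition, each gene's coefficient of variation CV = σ/μ is computed
across strains (sample σ, n−1 denominator; pairwise-complete; genes with
fewer than 3 values or non-positive mean are flagged unusable). The pooled CV
distribution is decomposed into two normal components by EM:

* initialization by a median split (below/above), weights ½/½;
* convergence when the log-likelihood gain falls below `tol` (default 1e-8,
  max 500 iterations); the log-likelihood sequence is checked to be
  non-decreasing, the EM guarantee;
* a collapsing component (σ → 0 or emptied) triggers a jittered restart, up
  to 5 times, then a hard error — constant data has no two-component
  decomposition;
* components are relabelled so component 2 has the larger mean.

A gene is *variable* when its posterior responsibility for the higher-CV
component exceeds `resp_cutoff` (default 0.5 — the standard EM decision rule;
the density-crossing point is available via `CVMixture.crossing_point` for a
threshold-style boundary) **and** its mean expression is at least `mean_floor`
(default 8 log2 units; the floor is applied to the per-condition mean). The
per-condition selections are merged by union, with provenance retained.
Selection is monotone in the responsibility cutoff by construction.

## Co-expression network and modules

Unsigned adjacency a_ij = |cor(x_i, x_j)|^β (Pearson, pairwise-complete with
a minimum of 3 shared strains; a signed variant ((1+cor)/2)^β is available by
flag). β is chosen by the scale-free topology criterion: for each candidate
power (default 1–20) the connectivity k_i = Σ_{j≠i} a_ij is binned on an
equal-width grid, log10 p(k) is regressed on log10 k̄ per bin, and the fit is
reported as −sign(slope)·R² so that an *increasing* degree distribution can
never look scale-free. The smallest β with signed R² ≥ 0.8 wins; if none
reaches the target the argmax is used with a logged warning. Mean
connectivity is strictly decreasing in β for any matrix with off-diagonal
entries < 1.

Topological overlap is the standard unsigned form

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,

computed by one matrix product with the diagonal zeroed; TOM_ii = 1. Modules
come from average-linkage hierarchical clustering on 1 − TOM with a static
branch cut at 0.99 of the maximum merge height; clusters below
`min_module_size` (default 30) join the grey bucket. The static cut is the
default because it is fully reproducible from two parameters and recovers
planted structure reliably at this problem scale; the adaptive ("dynamic")
cutting family trades that transparency for sensitivity to nested splits we
do not need here. Modules are labelled M1, M2, … in decreasing size order —
label identity is cosmetic; only partitions are compared anywhere.

Each module's eigengene is the first right-singular vector of its
gene-standardized submatrix, scaled to unit variance, sign-fixed so that it
correlates non-negatively with the module-average expression. kME is the
correlation of a gene with its own module's eigengene; intramodular
connectivity k_in sums a gene's adjacency to the other members.

The combined-network analysis concatenates the four condition matrices
column-wise with condition-tagged strain labels, so one network is fitted to
4 × n_strains pseudo-samples.

## Module statistics

* **Condition profile.** E_ij = module-average expression of strain i under
  condition j.
* **Pattern ANOVA.** One-way fixed-effects ANOVA of E_ij on condition,
  E_ij = μ + T_i + ε_ij, F = MS_between/MS_within, p from F(c−1, N−c).
* **Pattern classification.** Deltas are taken against NOS; a condition is
  up/down when |Δ| ≥ δ_min (default 0.1 log2 units — configurable; the
  pattern definitions themselves are qualitative). Pattern 1: NOE up, RSE
  back at baseline. Pattern 2: NOE down, RSE back. Pattern 3: RSS, NOE and
  RSE up with RSE exceeding both. Pattern 4: RSS up, NOE and RSE down-or-
  flat. A module matching zero or several patterns is reported
  *unclassified* rather than guessed; the classifier is invariant to adding a
  constant to all four means.
* **Trait correlation.** Pearson r between eigengene and trait on shared
  strains (≥ 4), p two-sided from t = r√((n−2)/(1−r²)); the output carries a
  display mask at |p| < 0.1 mirroring the conventional heat-map rule.
* **Enrichment.** 2×2 Fisher exact test of module × gene set within a
  universe (default: the genes entering the network). Two-sided p is the
  headline at α = 0.05; the one-sided (greater) p is reported alongside since
  over-representation is directional. A Benjamini–Hochberg column is emitted
  for reference; the raw thresholds remain the operative defaults.

## Preservation and specificity

For every non-grey module pair across two conditions, the shared-gene count
is tested with the hypergeometric upper tail (≡ one-sided Fisher) in the
intersection of the two conditions' gene universes — the conservative
universe choice. Significance is p < 0.01; the two-sided p is also reported.
A module is condition-specific iff it has no significant counterpart in any
module of every comparison condition. Preserved-module counts are reported
under both conventions (once per module with ≥ 1 significant match, and per
significant pair), since the two are often conflated.

## PPI overlay

Interactions with combined score strictly greater than 700 are high-
confidence (the boundary score 700 itself is excluded); duplicate unordered
pairs collapse to the maximum score; an optional 2-column mapping translates
protein to gene identifiers, dropping unmapped proteins with a logged count.
A *common interaction* is a retained PPI edge whose endpoints carry the same
non-grey module label (a stricter mode additionally requires co-expression
adjacency ≥ 0.1 between the endpoints). Subnetworks are connected components
of the common interactions within one module, reported at ≥ 5 nodes (a floor
that suppresses trivial pairs/triangles), exported as SIF/GraphML plus a
node-attribute table (module, kME, k_in) for Cytoscape.

## QTL mapping and causal orienting

Single-marker regression: OLS of trait on marker code,
LRS = n·ln(RSS₀/RSS₁) against the intercept-only null, LOD = LRS/(2 ln 10)
(so LRS 15 ⇔ LOD ≈ 3.26). Monomorphic markers are skipped; a perfect fit is
capped at LRS = 10⁶ and flagged so rankings stay total. The eQTL scan applies
the same statistic per gene × marker with a cis flag for same-chromosome
markers within a configurable window (default 10 map units; on dense RI maps
the *peak* marker of a real signal wanders within the linked region — peak
location should be read at the window, not the single-marker, scale).

Causal orienting fits, per (marker G, gene X, trait Y) triplet, the five
single-anchor trivariate Gaussian path models by maximum likelihood,
minimizing F_ML = ln|Σ(θ)| − ln|S| + tr(S·Σ(θ)⁻¹) − 3 on standardized data;
χ² = (n−1)·F_ML at the optimum with df = 1, p from χ²(1):

1. chain G→X→Y — testable constraint r_GY = r_GX·r_XY;
2. reactive chain G→Y→X — r_GX = r_GY·r_XY;
3. common cause X←G→Y — r_XY = r_GX·r_GY;
4. collider G→X←Y — r_GY = 0;
5. collider G→Y←X — r_GX = 0.

Models 1–3 impose a conditional independence; their ML optimum is the
Gaussian graphical-model fit, reached exactly over the two free correlations
(it matches the closed-form zero-partial-correlation likelihood ratio). The
collider models impose a *marginal* independence — a covariance-graph model —
where the variances must remain free parameters: pinning them to 1 inflates
the fit statistic (by ≈ 0.3 at n = 200 with strong nuisance correlations)
and visibly miscalibrates the χ²(1) p-values. They are therefore fitted over
a path parametrization (two collider paths plus three variances), which is
positive definite over the whole search domain. Calibration of all five
models is verified by Kolmogorov–Smirnov tests on the p-values under their
own generating model.

LEO = log₁₀(p₁ / max(p₂..p₅)); the forward orientation only is screened, and
the decision threshold is 0.5 (a 10^0.5 ≈ 3.2-fold better fit; LEO 1 is
ten-fold). Zero p-values are floored at the smallest positive float and
flagged. The gene screen computes LEO per (gene, trait) against one anchor
marker (typically the trait's peak-LRS marker), ranks genes by their maximum
score, and flags threshold passers. At a 41-strain panel a single triplet's
LEO is noisy (the score's sampling spread spans the threshold); ranking and
specificity — no passers in null modules — are the robust read-outs at that
size, which is how the screen is validated.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions:

* **Genotypes.** Default 200 markers on 5 chromosomes at 2 cM spacing, 41
  strains. Per strain and chromosome, the first allele is Bernoulli(0.5) and
  subsequent markers recombine with the Haldane fraction
  r = (1 − e^(−2d/100))/2; strains are independent. (RI panels have somewhat
  inflated effective recombination; irrelevant to the statistics tested and
  ignored.)
* **Expression.** 3000 genes; nine planted modules — two per condition
  pattern (sizes 150/120, 100/90, 80/70, 60/50) plus one 60-gene NOS-only
  module so cross-condition specificity has a planted positive. Each module
  has a latent strain factor *shared across conditions* (a strain's genetic
  effect does not depend on treatment); condition patterns enter as mean
  shifts of ±δ (default 0.5 log2 units; pattern 3 reaches +2δ under RSE).
  Member genes load as √ρ_g·f + √(1−ρ_g)·noise with per-gene signal fraction
  ρ_g = ρ^e, e ~ U(0.4, 2.5) around the module's ρ (default 0.7): membership
  strength spreads the way kME spreads in real modules. Background genes
  carry a weak Beta(1, 30) loading onto one random module factor (soft
  membership). This heterogeneity is what gives the connectivity
  distribution its heavy tail — with homogeneous loadings and fully
  independent background the network is not remotely scale-free and the power
  criterion has nothing to grip; with it, the signed R² curve saturates past
  0.8 at β ≈ 7–10, the regime the criterion is designed for.
* **CV structure.** Per-gene total CV is drawn from the two-component normal
  mixture 0.7·N(0.05, 0.01²) + 0.3·N(0.15, 0.03²); module genes are always
  variable, 8% of background genes are variable, and 10% of background genes
  get means in (6.0, 7.8) to exercise the mean ≥ 8 filter. The grand mean is
  9.0 (σ 0.4) log2 units.
* **Phenotypes.** Each causal triplet wires one marker, one module factor and
  one trait according to its true model id (the five structures above),
  effects b1 = b2 = 0.8, trait noise σ 0.6. Because models 2 and 4 make
  expression depend on the phenotype, factors and traits are drawn jointly in
  one latent step consumed by both generators. Pure-noise traits are included
  as negative controls. Defaults plant three forward chains plus one triplet
  under each alternative model.
* **PPI.** 25% of within-module gene pairs receive scores uniform on
  (700, 1000] (the planted subnetwork signal, recorded in the truth record);
  2000 random pairs receive scores uniform on [150, 1000].
* **Determinism.** One seed, fanned out to independent streams per component
  via `SeedSequence.spawn`; identical design + seed gives bit-identical
  output. An option drops k random strains per condition to emulate
  unbalanced panels (off by default, flagged in the truth record).

What the generator does **not** emulate: probe-level noise, sex or batch
effects, within-strain replicates, heavy-tailed expression noise, correlated
traits, genuine biological pathway structure in the PPI layer, or the real
panels' per-condition strain differences (unless the drop option is used).
Passing tests therefore demonstrate that the *statistical machinery*
recovers planted structure under Gaussian strain-mean conditions — not that
any particular biological finding would replicate.

## Numerical choices and degenerate inputs

* Correlations are pairwise-complete with a 3-shared-strain minimum; below
  that, and for zero-variance genes, the correlation is set to 0 with a
  warning.
* Eigengene sign: non-negative correlation with the module-average
  expression; single-gene modules reduce to the standardized gene.
* ANOVA with zero within-group variance and unequal means reports F = ∞,
  p = 0, flagged as a boundary.
* Fisher tests use exact hypergeometric machinery throughout; the test suite
  checks them against an independent `math.comb` summation oracle.
* SEM optimum: Nelder-Mead from the sample-moment start (tolerances 1e-9 /
  1e-13); non-PD candidates get a large finite penalty; agreement with an
  independent grid/multi-start minimizer is tested to 1e-4 on the χ² scale.
* Infinite-fit LRS capped at 10⁶, flagged.
* Stage seeds in the pipeline derive from the global seed via
  `SeedSequence.spawn`, so each stage is independently reproducible.

## Problem sizes used by the test suite and acceptance script

The suite exercises the full default design (41 strains × 4 conditions, 3000
genes) for recovery tests: module recovery over 5 seeds, mixture recovery
over 20 seeds, SEM calibration at 500 replicates per model, orientation
recovery at 100 replicates per model (n = 200, effects 0.8), screen recovery
over 12 seeds, and null-LEO specificity over 20 seeds. The acceptance script
repeats the pipeline end to end at the same design with orientation at 40
replicates per model and specificity over 12 seeds. These sizes were chosen
so the complete run stays comfortably interactive on a single CPU while the
binomial noise on every reported rate stays well inside its decision margin.

## Known limitations

* The static branch cut needs a sensible `min_module_size` for small gene
  sets (tests use 15–20 at a few hundred genes).
* The screen's LEO is anchor-marker specific; it does not search over
  markers, mirroring the peak-marker usage it models.
* Only the five single-anchor SEMs are implemented; no multi-anchor or
  network-neighbour edge orienting, no RMSEA-style fit indices.
* No block-wise network approximation: gene sets much beyond ~20k would need
  memory-aware TOM computation.
* GO-graph-aware enrichment (term offspring propagation) is out of scope; a
  flat GMT collection stands in.
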