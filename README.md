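# bxdnet

Systems-genetics analysis of strain-panel transcriptomes: weighted gene
co-expression networks, condition-pattern and trait statistics,
cross-condition module specificity, protein-interaction subnetwork overlay,
and SEM-based causal edge orienting from genotype through gene expression to
phenotype.

## Who this is for

Researchers analysing strain-mean expression from recombinant-inbred (RI)
panels — e.g. BXD mice measured under several treatment conditions — who want
to go from per-condition log2 expression matrices, a biallelic genotype map,
behavioural traits and a scored protein-interaction list to: variable-gene
selection, co-expression modules with eigengenes, condition patterns,
module–trait correlations, condition-specific modules, PPI-supported
subnetworks, and ranked candidate causal genes. A synthetic data generator
with complete ground truth makes every step testable end to end.

## The methods, briefly

**Variable genes.** Per condition, each gene's coefficient of variation
CV = σ/μ across strains is computed on the log2 scale. The CV distribution is
decomposed into two normal components with an EM algorithm; genes whose
posterior responsibility for the higher-CV component exceeds 0.5 and whose
mean expression is at least 8 log2 units are kept, and per-condition
selections are merged by union.

**Co-expression network.** Unsigned weighted adjacency
a<sub>ij</sub> = |cor(x<sub>i</sub>, x<sub>j</sub>)|<sup>β</sup> with β chosen
as the smallest power whose scale-free fit R² reaches 0.8. Topological
overlap

TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) / (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),  ℓ<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub>a<sub>uj</sub>,  k<sub>i</sub> = Σ<sub>u≠i</sub> a<sub>iu</sub>

feeds average-linkage clustering on 1 − TOM; branches are cut and clusters
below the minimum size go to the grey (unassigned) bucket. Each module gets
an eigengene (first principal component of its standardized expression), per-
gene kME = cor(gene, own ME) and intramodular connectivity k<sub>in</sub>.

**Module statistics.** Module-average expression E<sub>ij</sub> (strain i,
condition j) is classified into four condition patterns (treatment-induced
up/down shifts with restoration, rescue, amplification or reduction) and
tested by one-way ANOVA E<sub>ij</sub> = μ + T<sub>i</sub> + ε<sub>ij</sub>.
Eigengenes are correlated with traits (Pearson r, two-sided t-test p with
the |p| < 0.1 display rule). Gene-set over-representation uses the 2×2
Fisher exact test at p < 0.05.

**Preservation and specificity.** Module pairs across conditions are tested
for shared-gene overlap (hypergeometric/Fisher, p < 0.01). A module is
condition-specific when no module of any other condition overlaps it
significantly.

**PPI subnetworks.** STRING-style interactions with combined score
strictly greater than 700 are mapped onto modules; edges with both endpoints
in the same non-grey module are "common interactions", and their connected
components (≥ 5 genes) are the reported subnetworks, exportable as
SIF/GraphML for Cytoscape.

**QTL and causal orienting.** Single-marker regression reports
LRS = n·ln(RSS₀/RSS₁) and LOD = LRS/(2 ln 10) (LRS 15 ≈ LOD 3.26). For each
(marker G, gene X, trait Y) triplet, five single-anchor structural equation
models are fitted by maximum likelihood — the causal chain G→X→Y, the
reactive chain G→Y→X, the common-cause X←G→Y, and the colliders G→X←Y and
G→Y←X — each contributing a χ²(1) model-fit p-value. The local edge orienting
score LEO = log₁₀(p₁ / max(p₂..p₅)) quantifies how much better the causal
chain fits: LEO = 1 means ten-fold, and the decision threshold 0.5 means a
10<sup>0.5</sup> ≈ 3.2-fold better fit.

## Worked example

```python
import pandas as pd
from bxdnet import simulate, select_for_conditions, ModuleDetector
from bxdnet.datamodel import ExpressionMatrix
from bxdnet.module_stats import summarize_patterns

ds = simulate(seed=1)   # 41 strains x 4 conditions, 3000 genes, truth known
merged, fits, _ = select_for_conditions(ds.expression, seed=0)
print(f"selected {len(merged)} variable genes "
      f"(CV components: {fits['NOS'].means.round(3)})")

genes = sorted(merged.genes)
parts = []
for cond, e in ds.expression.items():
    sub = e.data.reindex(genes)
    sub.columns = [f"{cond}:{s}" for s in sub.columns]
    parts.append(sub)
comb = ExpressionMatrix(pd.concat(parts, axis=1), condition="combined")

det = ModuleDetector().fit(comb)
print(f"soft threshold beta = {det.power_}")
summary = summarize_patterns(ds.expression, det.modules_.assignment)
print(summary.table[["mean_NOS", "mean_RSS", "mean_NOE", "mean_RSE",
                     "pattern", "F", "p"]].round(3))
```

prints

```
selected 975 variable genes (CV components: [0.049 0.147])
soft threshold beta = 7
        mean_NOS  mean_RSS  mean_NOE  mean_RSE  pattern      F      p
module
M1         9.036     9.016     9.526     9.017        1  2.228  0.087
M2         9.017     9.028     9.504     9.012        1  2.088  0.104
M3         9.031     9.049     8.573     9.040        2  1.941  0.125
M4         9.014     9.009     8.514     8.994        2  2.325  0.077
M5         9.085     9.552     9.564    10.058        3  5.568  0.001
M6         9.104     9.596     9.556    10.081        3  5.779  0.001
M7         9.041     9.521     8.526     8.531        4  7.286  0.000
M8         8.969     9.518     8.476     8.499        4  7.818  0.000
```

The EM separates the invariable (CV ≈ 0.05) from the variable (CV ≈ 0.15)
population; the eight always-present planted modules are recovered with the
correct sizes, and each one's condition-mean profile is classified into its
true pattern (e.g. M5/M6 rise under stress and alcohol and double the shift
under the combination — pattern 3).

The same steps are available from the shell:

```bash
bxdnet simulate --seed 1 --out data/
bxdnet run --config config.yaml     # select-genes -> network -> stats ->
                                    # preserve -> ppi -> qtl -> neo
```

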