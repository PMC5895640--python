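"""Synthetic BXD-like data with known ground truth.

The generator emulates the study conditions the pipeline is designed for:

* RI-style genotypes — per strain, alleles follow a Markov chain along each
  chromosome with recombination fraction given by the Haldane map function
  ``r = (1 - exp(-2 d / 100)) / 2`` for an inter-marker distance of ``d`` cM.
* Four-condition (NOS/RSS/NOE/RSE) log2 strain-mean expression with planted
  co-expressed modules.  Each module has a latent strain factor shared across
  conditions (a strain's genetic effect does not depend on treatment); member
  genes load on it as ``sqrt(rho_g) * f + sqrt(1 - rho_g) * noise`` where the
  per-gene signal fraction ``rho_g = rho ** e_g`` (``e_g`` uniform on
  [0.4, 2.5]) spreads module membership strength the way kME spreads in real
  modules; background genes carry a weak loading onto a random module factor
  (soft membership), giving the connectivity distribution the heavy tail the
  scale-free criterion expects.  Module means follow one of four condition
  patterns:

  1. NOE up, RSE back at baseline ("NOE Up -> RSE Restore")
  2. NOE down, RSE back at baseline ("NOE Down -> RSE Rescue")
  3. RSS and NOE up, RSE amplified to twice the shift
  4. RSS up, NOE and RSE down

* A two-population coefficient-of-variation structure (variable vs invariable
  genes) plus a low-expression background fraction, so the CV mixture and the
  mean >= 8 filter have real work to do.
* Anxiety-like phenotypes causally wired to genotype -> module -> trait
  chains, with alternative-model triplets (reactive, common-cause and the two
  collider structures) and pure-noise negative-control traits.
* A PPI layer whose high-confidence edges partially overlap planted modules.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITIONS,
    GREY,
    ExpressionMatrix,
    GenotypeMatrix,
    ModuleAssignment,
    PhenotypeTable,
    PPIEdgeList,
)

#: Per-condition mean shift, in units of delta, for the four module patterns.
PATTERN_SHIFTS = {
    1: {"NOS": 0.0, "RSS": 0.0, "NOE": 1.0, "RSE": 0.0},
    2: {"NOS": 0.0, "RSS": 0.0, "NOE": -1.0, "RSE": 0.0},
    3: {"NOS": 0.0, "RSS": 1.0, "NOE": 1.0, "RSE": 2.0},
    4: {"NOS": 0.0, "RSS": 1.0, "NOE": -1.0, "RSE": -1.0},
}


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    pattern: int  # 1..4, see PATTERN_SHIFTS
    rho: float = 0.7  # within-module gene-gene correlation
    conditions: tuple[str, ...] = CONDITIONS  # where the co-expression exists

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_SHIFTS:
            raise ValueError(f"pattern must be 1..4, got {self.pattern}")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")


@dataclass
class CausalTriplet:
    """Genotype/module/phenotype wiring for one trait.

    ``model`` selects the generating structure among the five single-anchor
    models: 1 chain G->X->Y, 2 reactive chain G->Y->X, 3 common cause
    X<-G->Y, 4 collider G->X<-Y, 5 collider G->Y<-X (X is the module factor).
    """

    marker_index: int
    module_index: int
    phenotype: str
    b1: float = 0.8
    b2: float = 0.8
    noise_sd: float = 0.6
    model: int = 1

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4, 5):
            raise ValueError("model must be 1..5")


def _default_modules() -> list[ModuleSpec]:
    # two modules per condition pattern, plus one NOS-only module so that
    # cross-condition specificity has a planted positive
    return [
        ModuleSpec(150, 1), ModuleSpec(120, 1),
        ModuleSpec(100, 2), ModuleSpec(90, 2),
        ModuleSpec(80, 3), ModuleSpec(70, 3),
        ModuleSpec(60, 4), ModuleSpec(50, 4),
        ModuleSpec(60, 1, conditions=("NOS",)),
    ]


def _default_triplets() -> list[CausalTriplet]:
    return [
        CausalTriplet(20, 0, "ACTCNT_RSS", model=1),
        CausalTriplet(60, 2, "ACTCNT_NOE", model=1),
        CausalTriplet(100, 4, "OPEN_RSE", model=1),
        CausalTriplet(140, 1, "ALT_MODEL2", model=2),
        CausalTriplet(180, 3, "ALT_MODEL3", model=3),
        CausalTriplet(30, 5, "ALT_MODEL4", model=4),
        CausalTriplet(70, 6, "ALT_MODEL5", model=5),
    ]


@dataclass
class SyntheticDesign:
    """Full specification of one synthetic dataset."""

    n_strains: int = 41
    n_genes: int = 3000
    n_markers: int = 200
    n_chromosomes: int = 5
    marker_spacing_cm: float = 2.0
    modules: list[ModuleSpec] = field(default_factory=_default_modules)
    causal_triplets: list[CausalTriplet] = field(default_factory=_default_triplets)
    n_noise_traits: int = 2
    delta: float = 0.5  # pattern shift, log2 units
    grand_mean: float = 9.0  # log2 units; keeps the mean >= 8 filter meaningful
    gene_mean_sd: float = 0.4
    low_expr_fraction: float = 0.10  # background genes pushed below the mean floor
    low_expr_range: tuple[float, float] = (6.0, 7.8)
    # two-component CV mixture: (weight, mean, sd) per component
    cv_invariable: tuple[float, float, float] = (0.7, 0.05, 0.01)
    cv_variable: tuple[float, float, float] = (0.3, 0.15, 0.03)
    variable_background_fraction: float = 0.08
    loading_exponent_range: tuple[float, float] = (0.4, 2.5)  # rho_g = rho**e_g
    background_crosstalk_beta: float = 30.0  # bg loading ~ Beta(1, this)
    ppi_planted_fraction: float = 0.25  # of within-module pairs, scores > 700
    ppi_n_random_edges: int = 2000
    drop_strains_per_condition: int = 0  # emulate unbalanced panels
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for t in self.causal_triplets:
            if t.module_index >= len(self.modules):
                raise ValueError(f"triplet references unknown module {t.module_index}")
            if t.marker_index >= self.n_markers:
                raise ValueError(f"triplet references unknown marker {t.marker_index}")
        counts = [t.module_index for t in self.causal_triplets]
        if len(set(counts)) != len(counts):
            raise ValueError("each module may appear in at most one causal triplet")

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.modules))]


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    module_labels: pd.Series  # gene -> planted module label or grey
    module_patterns: dict[str, int]
    module_conditions: dict[str, tuple[str, ...]]
    variable_flags: pd.Series  # gene -> bool
    causal_triplets: list[dict]  # marker, module, phenotype, model, b1, b2
    planted_ppi_edges: set[tuple[str, str]]
    gene_positions: pd.DataFrame  # chrom, pos per gene
    balanced_panels: bool = True

    def assignment(self) -> ModuleAssignment:
        return ModuleAssignment(self.module_labels.copy())


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    expression: dict[str, ExpressionMatrix]
    phenotypes: PhenotypeTable
    ppi: PPIEdgeList
    truth: TruthRecord
    factors: pd.DataFrame  # module label -> latent strain factor


def _seeds(design: SyntheticDesign) -> dict[str, np.random.Generator]:
    names = ["genotypes", "latents", "expression", "ppi", "positions", "panels"]
    children = np.random.SeedSequence(design.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def generate_genotypes(design: SyntheticDesign) -> GenotypeMatrix:
    """RI-style genotypes: independent strains, Markov chain per chromosome."""
    rng = _seeds(design)["genotypes"]
    per_chrom = int(np.ceil(design.n_markers / design.n_chromosomes))
    chrom, pos = [], []
    for c in range(design.n_chromosomes):
        k = min(per_chrom, design.n_markers - c * per_chrom)
        chrom += [f"chr{c + 1}"] * k
        pos += list(np.arange(k) * design.marker_spacing_cm)
    chrom, pos = chrom[: design.n_markers], pos[: design.n_markers]
    codes = np.empty((design.n_markers, design.n_strains))
    i = 0
    for c in range(design.n_chromosomes):
        k = chrom.count(f"chr{c + 1}")
        block = np.empty((k, design.n_strains))
        block[0] = rng.integers(0, 2, design.n_strains)
        d = np.diff(pos[i:i + k])
        for j in range(1, k):
            r = haldane_r(d[j - 1])
            flip = rng.random(design.n_strains) < r
            block[j] = np.where(flip, 1 - block[j - 1], block[j - 1])
        codes[i:i + k] = block
        i += k
    counters: dict[str, int] = {}
    markers = []
    for c in chrom:
        counters[c] = counters.get(c, 0) + 1
        markers.append(f"{c}_m{counters[c]:03d}")
    strains = [f"BXD{s + 1:03d}" for s in range(design.n_strains)]
    codes_df = pd.DataFrame(codes, index=markers, columns=strains)
    mmap = pd.DataFrame({"chrom": chrom, "pos": pos}, index=markers)
    return GenotypeMatrix(codes_df, mmap, pos_unit="cM")


def _latents(design: SyntheticDesign, genotypes: GenotypeMatrix):
    """Module strain-factors and causal trait vectors, simulated jointly.

    Models 2 and 4 make the module factor depend on the phenotype, so factors
    and traits must be drawn together; both the expression and the phenotype
    generators consume this one deterministic draw.
    """
    rng = _seeds(design)["latents"]
    n = design.n_strains
    labels = design.module_labels
    factors = pd.DataFrame(
        rng.standard_normal((n, len(labels))),
        index=genotypes.strains, columns=labels,
    )
    traits: dict[str, np.ndarray] = {}
    for t in design.causal_triplets:
        g = genotypes.codes.iloc[t.marker_index].to_numpy()
        gc = g - g.mean()
        z = factors[labels[t.module_index]].to_numpy()
        e = rng.standard_normal(n) * t.noise_sd
        if t.model == 1:      # G -> X -> Y
            x = z + t.b1 * gc
            y = t.b2 * x + e
        elif t.model == 2:    # G -> Y -> X
            y = t.b1 * gc + e
            x = z + t.b2 * y
        elif t.model == 3:    # X <- G -> Y
            x = z + t.b1 * gc
            y = t.b2 * gc + e
        elif t.model == 4:    # G -> X <- Y
            y = rng.standard_normal(n)
            x = z + t.b1 * gc + t.b2 * y
        else:                 # G -> Y <- X
            x = z
            y = t.b1 * gc + t.b2 * x + e
        factors[labels[t.module_index]] = x
        traits[t.phenotype] = y
    for k in range(design.n_noise_traits):
        traits[f"NOISE{k + 1}"] = rng.standard_normal(n)
    return factors, traits


def _gene_table(design: SyntheticDesign, genotypes: GenotypeMatrix):
    """Per-gene truth: module, variable flag, mean, cv, position."""
    rng_pos = _seeds(design)["positions"]
    n = design.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]
    module = np.array([GREY] * n, dtype=object)
    i = 0
    for lab, spec in zip(design.module_labels, design.modules):
        module[i:i + spec.size] = lab
        i += spec.size
    is_bg = module == GREY
    variable = ~is_bg
    variable[is_bg] = rng_pos.random(is_bg.sum()) < design.variable_background_fraction

    w_inv, mu_inv, sd_inv = design.cv_invariable
    w_var, mu_var, sd_var = design.cv_variable
    if abs(w_inv + w_var - 1.0) > 1e-9:
        raise ValueError("CV mixture weights must sum to 1")
    cv = np.where(
        variable,
        rng_pos.normal(mu_var, sd_var, n),
        rng_pos.normal(mu_inv, sd_inv, n),
    )
    cv = np.clip(cv, 1e-3, None)

    mean = rng_pos.normal(design.grand_mean, design.gene_mean_sd, n)
    low = is_bg & (rng_pos.random(n) < design.low_expr_fraction)
    mean[low] = rng_pos.uniform(*design.low_expr_range, low.sum())

    # per-gene signal fraction: module genes rho**e_g; background genes a weak
    # loading onto one random module factor (soft membership / cross-talk)
    lo_e, hi_e = design.loading_exponent_range
    exponent = rng_pos.uniform(lo_e, hi_e, n)
    rho_gene = np.zeros(n)
    for lab, spec in zip(design.module_labels, design.modules):
        sel = module == lab
        rho_gene[sel] = spec.rho ** exponent[sel]
    rho_gene[is_bg] = rng_pos.beta(1.0, design.background_crosstalk_beta, is_bg.sum())
    bg_factor = rng_pos.integers(0, max(len(design.modules), 1), n)

    # positions: causal-module genes sit near their marker (cis), rest random
    mmap = genotypes.marker_map
    chrom = rng_pos.choice(mmap["chrom"].unique(), n)
    maxpos = float(mmap["pos"].max())
    pos = rng_pos.uniform(0, maxpos, n)
    for t in design.causal_triplets:
        lab = design.module_labels[t.module_index]
        sel = module == lab
        mrow = mmap.iloc[t.marker_index]
        chrom[sel] = mrow["chrom"]
        pos[sel] = np.clip(
            mrow["pos"] + rng_pos.uniform(-5, 5, sel.sum()), 0, maxpos
        )
    return pd.DataFrame(
        {"gene": genes, "module": module, "variable": variable,
         "mean": mean, "cv": cv, "rho_gene": rho_gene, "bg_factor": bg_factor,
         "chrom": chrom, "pos": pos}
    ).set_index("gene")


def generate_expression(
    design: SyntheticDesign, genotypes: GenotypeMatrix
) -> dict[str, ExpressionMatrix]:
    """Four condition matrices with planted modules, patterns and CV structure."""
    return _generate_expression(design, genotypes)[0]


def _generate_expression(design: SyntheticDesign, genotypes: GenotypeMatrix):
    rng = _seeds(design)["expression"]
    rng_panel = _seeds(design)["panels"]
    factors, traits = _latents(design, genotypes)
    table = _gene_table(design, genotypes)
    n, m = design.n_strains, design.n_genes
    strains = genotypes.strains
    sd_gene = (table["cv"] * table["mean"]).to_numpy()

    # empirically standardize factors so within-module correlation is rho
    f_std = (factors - factors.mean()) / factors.std(ddof=0)

    rho_g = table["rho_gene"].to_numpy()
    out: dict[str, ExpressionMatrix] = {}
    for cond in CONDITIONS:
        vals = np.empty((m, n))
        eps = rng.standard_normal((m, n))
        for lab, spec in zip(design.module_labels, design.modules):
            sel = (table["module"] == lab).to_numpy()
            shift = PATTERN_SHIFTS[spec.pattern][cond] * design.delta
            if cond in spec.conditions:
                sig = (np.sqrt(rho_g[sel])[:, None] * f_std[lab].to_numpy()[None, :]
                       + np.sqrt(1 - rho_g[sel])[:, None] * eps[sel])
            else:
                sig = eps[sel]  # module absent here: independent noise
            vals[sel] = (table.loc[sel, "mean"].to_numpy()[:, None] + shift
                         + sd_gene[sel, None] * sig)
        bg = (table["module"] == GREY).to_numpy()
        f_all = f_std.to_numpy().T  # module x strain
        bg_sig = (np.sqrt(rho_g[bg])[:, None]
                  * f_all[table.loc[bg, "bg_factor"].to_numpy()]
                  + np.sqrt(1 - rho_g[bg])[:, None] * eps[bg])
        vals[bg] = table.loc[bg, "mean"].to_numpy()[:, None] + sd_gene[bg, None] * bg_sig
        cols = list(strains)
        df = pd.DataFrame(vals, index=table.index, columns=cols)
        if design.drop_strains_per_condition > 0:
            keep = sorted(rng_panel.choice(
                n, n - design.drop_strains_per_condition, replace=False))
            df = df.iloc[:, keep]
        out[cond] = ExpressionMatrix(df, condition=cond)
    return out, factors, traits, table


def generate_phenotypes(
    design: SyntheticDesign,
    genotypes: GenotypeMatrix,
    expression: dict[str, ExpressionMatrix] | None = None,
) -> PhenotypeTable:
    """Traits wired to the module factors per their causal model."""
    _, traits = _latents(design, genotypes)
    data = pd.DataFrame(traits, index=genotypes.strains)
    return PhenotypeTable(data)


def generate_ppi(design: SyntheticDesign, truth: TruthRecord) -> PPIEdgeList:
    """Scored edges: planted within-module (> 700) plus random background."""
    rng = _seeds(design)["ppi"]
    genes = np.array(truth.module_labels.index)
    labels = truth.module_labels.to_numpy()
    rows: list[tuple[str, str, int]] = []
    planted: set[tuple[str, str]] = set()
    for lab in truth.module_patterns:
        members = genes[labels == lab]
        k = len(members)
        if k < 2:
            continue
        iu, ju = np.triu_indices(k, 1)
        n_pairs = len(iu)
        n_take = int(round(design.ppi_planted_fraction * n_pairs))
        take = rng.choice(n_pairs, size=n_take, replace=False)
        for t in take:
            u, v = members[iu[t]], members[ju[t]]
            if v < u:
                u, v = v, u
            planted.add((u, v))
            rows.append((u, v, int(rng.integers(701, 1001))))
    for _ in range(design.ppi_n_random_edges):
        u, v = rng.choice(len(genes), 2, replace=False)
        a, b = genes[u], genes[v]
        if b < a:
            a, b = b, a
        if (a, b) in planted:
            continue
        rows.append((a, b, int(rng.integers(150, 1001))))
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "score"])
    truth.planted_ppi_edges = planted
    return PPIEdgeList(edges)


def simulate(design: SyntheticDesign | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete dataset plus ground truth.

    ``seed`` overrides ``design.seed`` when given.  Identical design and seed
    give bit-identical outputs.
    """
    design = design or SyntheticDesign()
    if seed is not None:
        design = SyntheticDesign(**{**asdict_shallow(design), "seed": seed})
    genotypes = generate_genotypes(design)
    expression, factors, traits, table = _generate_expression(design, genotypes)
    phenotypes = PhenotypeTable(pd.DataFrame(traits, index=genotypes.strains))
    truth = TruthRecord(
        module_labels=table["module"].copy(),
        module_patterns={
            lab: spec.pattern
            for lab, spec in zip(design.module_labels, design.modules)
        },
        module_conditions={
            lab: tuple(spec.conditions)
            for lab, spec in zip(design.module_labels, design.modules)
        },
        variable_flags=table["variable"].copy(),
        causal_triplets=[
            {
                "marker": genotypes.markers[t.marker_index],
                "module": design.module_labels[t.module_index],
                "phenotype": t.phenotype,
                "model": t.model,
                "b1": t.b1,
                "b2": t.b2,
            }
            for t in design.causal_triplets
        ],
        planted_ppi_edges=set(),
        gene_positions=table[["chrom", "pos"]].copy(),
        balanced_panels=design.drop_strains_per_condition == 0,
    )
    ppi = generate_ppi(design, truth)  # also records planted edges in truth
    return SyntheticDataset(genotypes, expression, phenotypes, ppi, truth, factors)


def asdict_shallow(design: SyntheticDesign) -> dict:
    """Shallow dict of a design (module/triplet objects kept intact)."""
    return {f: getattr(design, f) for f in design.__dataclass_fields__}


def design_to_dict(design: SyntheticDesign) -> dict:
    """JSON/YAML-serializable dict of a design."""
    return asdict(design)


def design_from_dict(d: dict) -> SyntheticDesign:
    d = dict(d)
    if "modules" in d:
        d["modules"] = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(**{
                **m, "conditions": tuple(m.get("conditions", CONDITIONS))})
            for m in d["modules"]
        ]
    if "causal_triplets" in d:
        d["causal_triplets"] = [
            t if isinstance(t, CausalTriplet) else CausalTriplet(**t)
            for t in d["causal_triplets"]
        ]
    for key in ("low_expr_range", "cv_invariable", "cv_variable"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SyntheticDesign(**d)
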