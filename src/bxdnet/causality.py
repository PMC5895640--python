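"""Single-marker linkage and SEM-based causal edge orienting.

Marker regression reports the likelihood ratio statistic
``LRS = n * ln(RSS0 / RSS1)`` (null = intercept-only) with
``LOD = LRS / (2 ln 10)``.  Causal orientation fits, per
(marker G, gene X, phenotype Y) triplet, the five single-anchor trivariate
Gaussian path models

    1: G -> X -> Y        (testable constraint r_GY = r_GX * r_XY)
    2: G -> Y -> X        (r_GX = r_GY * r_XY)
    3: X <- G -> Y        (r_XY = r_GX * r_GY)
    4: G -> X <- Y        (r_GY = 0)
    5: G -> Y <- X        (r_GX = 0)

by maximum likelihood on the standardized correlation matrix, yielding a
chi-square model-fit statistic with one degree of freedom each.  The local
edge orienting (LEO) score is ``log10(p1 / max(p2..p5))``; a score of 0.5
(the decision threshold) means the forward chain fits 10^0.5 ~ 3.2 times
better than the best alternative, and a score of 1 means ten times better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import ExpressionMatrix, GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)

LOG10_FACTOR = 2.0 * np.log(10.0)  # LOD = LRS / (2 ln 10)
LRS_CAP = 1e6
_P_FLOOR = np.finfo(float).tiny


@dataclass
class QTLResult:
    trait: str
    marker: str
    lrs: float
    additive_effect: float
    n: int
    capped: bool = False

    @property
    def lod(self) -> float:
        return self.lrs / LOG10_FACTOR


@dataclass
class EQTLResult:
    gene: str
    marker: str
    lrs: float
    cis: bool
    window: float
    n: int

    @property
    def lod(self) -> float:
        return self.lrs / LOG10_FACTOR


@dataclass
class SEMModelFit:
    model_id: int
    chi2: float
    df: int
    p: float
    params: dict[str, float] = field(default_factory=dict)
    p_floored: bool = False


@dataclass
class LEOResult:
    marker: str
    gene: str
    phenotype: str
    fits: list[SEMModelFit]
    leo: float
    passes: bool

    @property
    def p_values(self) -> list[float]:
        return [f.p for f in self.fits]


def marker_regression(
    trait, marker, trait_name: str = "trait", marker_name: str = "marker",
    min_n: int = 8,
) -> QTLResult | None:
    """OLS of a trait on a 0/1 marker code; None for unusable markers."""
    y = np.asarray(trait, dtype=float)
    g = np.asarray(marker, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    n = y.size
    if n < min_n:
        return None
    if np.unique(g).size < 2:
        log.debug("monomorphic marker %s skipped", marker_name)
        return None
    gc = g - g.mean()
    yc = y - y.mean()
    beta = float(gc @ yc / (gc @ gc))
    rss0 = float(yc @ yc)
    rss1 = float(((yc - beta * gc) ** 2).sum())
    capped = False
    if rss0 == 0:
        lrs = 0.0
    elif rss1 <= rss0 * np.exp(-LRS_CAP / n):
        lrs, capped = LRS_CAP, True
    else:
        lrs = n * np.log(rss0 / rss1)
    return QTLResult(trait_name, marker_name, lrs, beta, n, capped)


def qtl_scan(
    phenotypes: PhenotypeTable, genotypes: GenotypeMatrix, min_n: int = 8
) -> pd.DataFrame:
    """Marker regression for every trait x marker pair (long format)."""
    shared = [s for s in phenotypes.strains if s in genotypes.strains]
    codes = genotypes.codes[shared]
    rows = []
    for trait in phenotypes.traits:
        y = phenotypes.data.loc[shared, trait]
        for marker in genotypes.markers:
            res = marker_regression(
                y.to_numpy(), codes.loc[marker].to_numpy(),
                trait_name=trait, marker_name=marker, min_n=min_n,
            )
            if res is not None:
                rows.append({
                    "trait": trait, "marker": marker, "lrs": res.lrs,
                    "lod": res.lod, "additive_effect": res.additive_effect,
                    "n": res.n, "capped": res.capped,
                })
    return pd.DataFrame(rows)


def peak_marker(qtl_table: pd.DataFrame, trait: str) -> str:
    """Marker with the highest LRS for a trait."""
    sub = qtl_table[qtl_table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no QTL rows for trait {trait!r}")
    return str(sub.loc[sub["lrs"].idxmax(), "marker"])


def eqtl_scan(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_positions: pd.DataFrame | None = None,
    cis_window: float = 10.0,
    lrs_min: float = 0.0,
) -> pd.DataFrame:
    """Marker regression of every gene on every marker.

    ``gene_positions`` (index gene, columns chrom/pos) enables the cis flag:
    same chromosome and distance <= ``cis_window`` (in the map's unit).
    Genes without a position are trans-only and flagged.  Rows with
    LRS < ``lrs_min`` are omitted to keep the output manageable.
    """
    shared = [s for s in expr.strains if s in genotypes.strains]
    x = expr.data[shared].to_numpy()
    g = genotypes.codes[shared].to_numpy()
    n = len(shared)
    # complete-data fast path: LRS = -n ln(1 - r^2)
    xz = (x - x.mean(axis=1, keepdims=True))
    xsd = x.std(axis=1, ddof=0)
    gz = (g - g.mean(axis=1, keepdims=True))
    gsd = g.std(axis=1, ddof=0)
    ok_gene = xsd > 0
    ok_marker = gsd > 0
    xn = np.where(ok_gene[:, None], xz / np.where(xsd == 0, 1, xsd)[:, None], 0.0)
    gn = np.where(ok_marker[:, None], gz / np.where(gsd == 0, 1, gsd)[:, None], 0.0)
    r = (xn @ gn.T) / n
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    lrs = -n * np.log(1 - r**2)
    mmap = genotypes.marker_map
    rows = []
    for i, gene in enumerate(expr.genes):
        if not ok_gene[i]:
            continue
        has_pos = gene_positions is not None and gene in gene_positions.index
        for j, marker in enumerate(genotypes.markers):
            if not ok_marker[j] or lrs[i, j] < lrs_min:
                continue
            cis = False
            if has_pos:
                grow = gene_positions.loc[gene]
                mrow = mmap.loc[marker]
                cis = (grow["chrom"] == mrow["chrom"]
                       and abs(float(grow["pos"]) - float(mrow["pos"])) <= cis_window)
            rows.append({
                "gene": gene, "marker": marker, "lrs": float(lrs[i, j]),
                "lod": float(lrs[i, j] / LOG10_FACTOR), "cis": cis,
                "has_position": has_pos, "window": cis_window, "n": n,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SEM model fitting

#: model id -> (constrained correlation index, kind); correlations ordered
#: (r_GX, r_GY, r_XY); kind "product" means the constrained entry equals the
#: product of the two free ones, "zero" means it is fixed at 0.
_MODEL_CONSTRAINTS = {
    1: (1, "product"),  # r_GY = r_GX * r_XY
    2: (0, "product"),  # r_GX = r_GY * r_XY
    3: (2, "product"),  # r_XY = r_GX * r_GY
    4: (1, "zero"),     # r_GY = 0
    5: (0, "zero"),     # r_GX = 0
}


def _corr_matrix(r_gx: float, r_gy: float, r_xy: float) -> np.ndarray:
    return np.array([
        [1.0, r_gx, r_gy],
        [r_gx, 1.0, r_xy],
        [r_gy, r_xy, 1.0],
    ])


_F_PENALTY = 1e10  # non-PD implied covariance: large finite penalty


def _f_ml(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return _F_PENALTY
    try:
        tr = float(np.trace(np.linalg.solve(sigma, s)))
    except np.linalg.LinAlgError:
        return _F_PENALTY
    return logdet - logdet_s + tr - 3.0


def fit_sem_model(g, x, y, model_id: int, min_n: int = 10) -> SEMModelFit:
    """Fit one single-anchor model by ML on the model-implied covariance.

    Variables are standardized and F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1)
    - 3 is minimized over the free parameters; chi2 = (n - 1) * F_ML at the
    optimum, df = 1, p from chi-square(1).

    Models 1-3 impose a conditional-independence constraint (a product rule
    on the correlations); their ML optimum is the Gaussian graphical-model
    fit, reached over the two free correlations with unit variances.  Models
    4 and 5 impose a *marginal* independence (one covariance fixed at zero, a
    covariance-graph model), where the variances must stay free or the fit
    statistic is inflated; they are minimized over the two free covariances
    plus the three variances.
    """
    if model_id not in _MODEL_CONSTRAINTS:
        raise ValueError(f"model_id must be 1..5, got {model_id}")
    arr = np.column_stack([
        np.asarray(g, dtype=float),
        np.asarray(x, dtype=float),
        np.asarray(y, dtype=float),
    ])
    arr = arr[np.isfinite(arr).all(axis=1)]
    n = arr.shape[0]
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete triples, have {n}")
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("zero-variance variable in SEM triplet")
    s = np.corrcoef(arr, rowvar=False)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("singular sample correlation matrix")
    c_idx, kind = _MODEL_CONSTRAINTS[model_id]
    sample = np.array([s[0, 1], s[0, 2], s[1, 2]])
    free_idx = [i for i in range(3) if i != c_idx]
    pairs = [(0, 1), (0, 2), (1, 2)]

    if kind == "product":
        def implied(theta: np.ndarray) -> np.ndarray:
            f = np.clip(theta, -0.999999, 0.999999)
            r = np.empty(3)
            r[free_idx[0]], r[free_idx[1]] = f
            r[c_idx] = f[0] * f[1]
            return _corr_matrix(*r)

        x0 = np.clip(sample[free_idx], -0.99, 0.99)
    else:
        # collider (covariance-graph) model: parametrize by the two paths
        # into the collider plus three variances, so the implied covariance
        # is positive definite over the whole search domain
        parents = list(pairs[c_idx])  # the marginally independent pair
        collider = ({0, 1, 2} - set(parents)).pop()

        def implied(theta: np.ndarray) -> np.ndarray:
            v1, v2, ve = np.abs(theta[:3]) + 1e-12
            a, b = theta[3], theta[4]
            sigma = np.zeros((3, 3))
            p1, p2 = parents
            sigma[p1, p1] = v1
            sigma[p2, p2] = v2
            sigma[p1, collider] = sigma[collider, p1] = a * v1
            sigma[p2, collider] = sigma[collider, p2] = b * v2
            sigma[collider, collider] = a * a * v1 + b * b * v2 + ve
            return sigma

        a0 = s[parents[0], collider]
        b0 = s[parents[1], collider]
        x0 = np.array([1.0, 1.0,
                       max(1.0 - a0 * a0 - b0 * b0, 0.1), a0, b0])

    def objective(theta: np.ndarray) -> float:
        return _f_ml(implied(theta), s, logdet_s)

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 5000},
    )
    if not np.isfinite(res.fun) or res.fun >= _F_PENALTY:
        raise RuntimeError(f"SEM model {model_id} did not converge: {res.message}")
    fmin = max(float(res.fun), 0.0)
    chi2 = (n - 1) * fmin
    p = float(stats.chi2.sf(chi2, df=1))
    floored = False
    if p <= 0.0:
        p, floored = _P_FLOOR, True
    sigma_hat = implied(res.x)
    d = np.sqrt(np.diag(sigma_hat))
    r_hat = sigma_hat / np.outer(d, d)
    return SEMModelFit(
        model_id=model_id, chi2=chi2, df=1, p=p,
        params={"r_gx": r_hat[0, 1], "r_gy": r_hat[0, 2], "r_xy": r_hat[1, 2]},
        p_floored=floored,
    )


def fit_all_models(g, x, y, min_n: int = 10) -> list[SEMModelFit]:
    return [fit_sem_model(g, x, y, m, min_n=min_n) for m in (1, 2, 3, 4, 5)]


def leo_score(
    fits: list[SEMModelFit],
    marker: str = "G", gene: str = "X", phenotype: str = "Y",
    threshold: float = 0.5,
) -> LEOResult:
    """LEO = log10(p1 / max(p2..p5)); forward orientation only."""
    if len(fits) != 5 or sorted(f.model_id for f in fits) != [1, 2, 3, 4, 5]:
        raise ValueError("leo_score needs exactly the five model fits")
    by_id = {f.model_id: f for f in fits}
    p1 = max(by_id[1].p, _P_FLOOR)
    p_alt = max(max(by_id[m].p for m in (2, 3, 4, 5)), _P_FLOOR)
    leo = float(np.log10(p1 / p_alt))
    return LEOResult(marker, gene, phenotype, [by_id[m] for m in (1, 2, 3, 4, 5)],
                     leo, leo >= threshold)


def screen_causal_genes(
    marker_codes,
    module_expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    marker_name: str = "marker",
    threshold: float = 0.5,
    kme_floor: pd.Series | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """LEO per (gene, phenotype) against one anchor marker, ranked by the
    gene's maximum score over phenotypes.

    ``kme_floor``, when given as (series of kME values, min value) semantics
    is handled by pre-filtering the expression matrix by the caller; here an
    optional series restricts genes to its index.
    """
    g = np.asarray(marker_codes, dtype=float)
    rows = []
    genes = module_expr.genes
    if kme_floor is not None:
        genes = [gn for gn in genes if gn in kme_floor.index]
    strains = module_expr.strains
    pheno = phenotypes.data.reindex(strains)
    for gene in genes:
        x = module_expr.data.loc[gene].to_numpy()
        for trait in phenotypes.traits:
            y = pheno[trait].to_numpy()
            try:
                fits = fit_all_models(g, x, y, min_n=min_n)
            except (ValueError, RuntimeError) as err:
                log.debug("skipping %s x %s: %s", gene, trait, err)
                continue
            res = leo_score(fits, marker_name, gene, trait, threshold)
            rows.append({
                "gene": gene, "phenotype": trait, "marker": marker_name,
                **{f"p{m}": res.fits[m - 1].p for m in (1, 2, 3, 4, 5)},
                "leo": res.leo, "passes": res.passes,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["max_leo"] = df.groupby("gene")["leo"].transform("max")
    df = df.sort_values(["max_leo", "gene", "leo"], ascending=[False, True, False])
    return df.reset_index(drop=True)
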