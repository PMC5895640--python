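"""Weighted gene co-expression network construction and module detection.

The network is the classic weighted construction: unsigned adjacency
``a_ij = |cor(x_i, x_j)|^beta`` with the soft threshold beta chosen by the
scale-free topology criterion, topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu,

average-linkage hierarchical clustering on ``1 - TOM``, branch cutting, and
module eigengenes (first principal component of the standardized module
expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datamodel import GREY, ExpressionMatrix, ModuleAssignment

log = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.8
    signed: bool = False
    min_module_size: int = 30
    cut_height_frac: float = 0.99  # of max merge height (static cut)
    min_shared_strains: int = 3


@dataclass
class PowerScan:
    table: pd.DataFrame  # index beta; columns: rsq (signed), mean_k


@dataclass
class ModuleSet:
    assignment: ModuleAssignment
    linkage: np.ndarray  # scipy merge tree
    eigengenes: pd.DataFrame  # module x strain, unit variance
    kme: pd.Series  # gene -> cor(gene, own-module ME); NaN for grey
    k_in: pd.Series  # gene -> intramodular connectivity
    sizes: pd.Series  # module -> size (excluding grey)


def pairwise_correlation(
    expr: ExpressionMatrix, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation between genes, pairwise-complete observations.

    Pairs with fewer than ``min_shared`` shared strains, and genes with zero
    variance, get correlation 0 (with a warning).
    """
    x = expr.values
    if not np.isnan(x).any():
        sd = x.std(axis=1, ddof=1)
        zero = sd == 0
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.where(zero, 1.0, sd * np.sqrt(x.shape[1] - 1))
        xn = xc / denom[:, None]
        c = xn @ xn.T
        if zero.any():
            log.warning("%d zero-variance gene(s); correlations set to 0", zero.sum())
            c[zero, :] = 0.0
            c[:, zero] = 0.0
        np.fill_diagonal(c, 1.0)
        c = np.clip(c, -1.0, 1.0)
        return pd.DataFrame(c, index=expr.genes, columns=expr.genes)
    df = expr.data.T  # pandas corr is pairwise-complete over columns
    c = df.corr(min_periods=min_shared).to_numpy()
    low = np.isnan(c)
    if low.any():
        log.warning("correlations with < %d shared strains set to 0", min_shared)
        c[low] = 0.0
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(np.clip(c, -1, 1), index=expr.genes, columns=expr.genes)


def adjacency(
    expr: ExpressionMatrix, beta: int, signed: bool = False,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Weighted adjacency ``|cor|^beta`` (or ``((1+cor)/2)^beta`` signed)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = pairwise_correlation(expr, min_shared=min_shared).to_numpy()
    a = ((1 + c) / 2) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.genes, columns=expr.genes)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix (diagonal 1)."""
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj over u != i,j (diagonal is zeroed)
    kmin = np.minimum.outer(k, k)
    t = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def _scale_free_rsq(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression."""
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    # equal-width bins over k; regress log10 p(k) on log10 mean-k per bin
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        logk.append(np.log10(k[sel].mean()))
        logp.append(np.log10(sel.mean()))
    logk, logp = np.asarray(logk), np.asarray(logp)
    if logk.size < 3 or np.ptp(logk) == 0:
        return 0.0
    slope, _ = np.polyfit(logk, logp, 1)
    r = np.corrcoef(logk, logp)[0, 1]
    return float(-np.sign(slope) * r**2)


def scan_powers(expr: ExpressionMatrix, params: NetworkParams | None = None) -> PowerScan:
    """Scale-free fit R^2 and mean connectivity for each candidate power."""
    params = params or NetworkParams()
    if expr.data.shape[0] < 30:
        log.warning("power scan on < 30 genes; scale-free fit is unreliable")
    if float(expr.data.std(axis=1, ddof=0).max()) == 0.0:
        raise ValueError("all-constant expression matrix")
    c = pairwise_correlation(expr, params.min_shared_strains).to_numpy()
    rows = []
    base = ((1 + c) / 2) if params.signed else np.abs(c)
    for beta in params.candidate_powers:
        a = base**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"beta": beta, "rsq": _scale_free_rsq(k), "mean_k": float(k.mean())})
    return PowerScan(pd.DataFrame(rows).set_index("beta"))


def pick_power(scan: PowerScan, params: NetworkParams | None = None) -> int:
    """Smallest power whose signed R^2 reaches the target, else argmax."""
    params = params or NetworkParams()
    tab = scan.table
    ok = tab.index[tab["rsq"] >= params.rsq_target]
    if len(ok):
        return int(ok[0])
    best = int(tab["rsq"].idxmax())
    log.warning(
        "no power reaches R^2 >= %.2f; using argmax beta=%d (R^2=%.3f)",
        params.rsq_target, best, tab.loc[best, "rsq"],
    )
    return best


def module_eigengene(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """First principal component of the gene-standardized module submatrix,
    unit variance, sign-fixed so cor(ME, module-average expression) >= 0."""
    sub = expr.data.loc[list(genes)]
    if sub.shape[0] < 1:
        raise ValueError("module must contain >= 1 gene")
    x = sub.to_numpy()
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("all-constant module; eigengene undefined")
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    z = np.nan_to_num(z)
    # first right-singular vector = strain loadings of the first PC
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    avg = z.mean(axis=0)
    if np.corrcoef(me, avg)[0, 1] < 0:
        me = -me
    return pd.Series(me, index=sub.columns, name="ME")


def _cut_static(link: np.ndarray, height_frac: float) -> np.ndarray:
    h = height_frac * link[:, 2].max()
    return fcluster(link, t=h, criterion="distance")


def detect_modules(
    tom_df: pd.DataFrame,
    expr: ExpressionMatrix,
    params: NetworkParams | None = None,
    adj: pd.DataFrame | None = None,
) -> ModuleSet:
    """Average-linkage clustering on ``1 - TOM``; static branch cut; clusters
    below ``min_module_size`` go to grey; labels M1..Mn by decreasing size."""
    params = params or NetworkParams()
    genes = list(tom_df.index)
    n = len(genes)
    if n < params.min_module_size:
        log.warning("fewer genes (%d) than min module size; all grey", n)
        assignment = ModuleAssignment(pd.Series(GREY, index=genes))
        empty = pd.Series(dtype=float)
        return ModuleSet(assignment, np.empty((0, 4)),
                         pd.DataFrame(columns=expr.strains),
                         pd.Series(np.nan, index=genes),
                         pd.Series(0.0, index=genes), empty)
    diss = 1.0 - tom_df.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0, None)
    link = linkage(squareform(diss, checks=False), method="average")
    raw = _cut_static(link, params.cut_height_frac)
    labels = pd.Series(raw, index=genes)
    counts = labels.value_counts()
    keep = counts.index[counts >= params.min_module_size]
    # order surviving clusters by decreasing size -> M1..Mn
    keep = sorted(keep, key=lambda c: (-counts[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(keep)}
    final = labels.map(lambda c: rename.get(c, GREY)).astype(str)
    assignment = ModuleAssignment(final)
    return _annotate(assignment, link, expr, tom_df, params, adj)


def _annotate(
    assignment: ModuleAssignment,
    link: np.ndarray,
    expr: ExpressionMatrix,
    tom_df: pd.DataFrame,
    params: NetworkParams,
    adj: pd.DataFrame | None,
) -> ModuleSet:
    genes = assignment.genes
    modules = assignment.modules()
    mes = {}
    for m in modules:
        mes[m] = module_eigengene(expr, sorted(assignment.members(m)))
    eigengenes = pd.DataFrame(mes).T
    eigengenes.index.name = "module"
    kme = pd.Series(np.nan, index=genes)
    for m in modules:
        members = sorted(assignment.members(m))
        sub = expr.data.loc[members]
        me = mes[m]
        z = sub.sub(sub.mean(axis=1), axis=0)
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = np.nan
        mez = me - me.mean()
        denom = sd * me.std(ddof=1) * (len(me) - 1)
        kme.loc[members] = (z @ mez) / denom
    if adj is None:
        a = tom_df  # fall back: TOM-based connectivity if adjacency not kept
    else:
        a = adj
    a_np = a.to_numpy().copy()
    np.fill_diagonal(a_np, 0.0)
    a_df = pd.DataFrame(a_np, index=a.index, columns=a.columns)
    k_in = pd.Series(0.0, index=genes)
    for m in modules:
        members = sorted(assignment.members(m))
        k_in.loc[members] = a_df.loc[members, members].sum(axis=1)
    sizes = pd.Series({m: assignment.size(m) for m in modules}, dtype=int)
    return ModuleSet(assignment, link, eigengenes, kme, k_in, sizes)


def module_membership(expr: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME of every gene for every module eigengene (genes x modules)."""
    x = expr.data
    out = {}
    for m in eigengenes.index:
        me = eigengenes.loc[m]
        z = x.sub(x.mean(axis=1), axis=0)
        sd = x.std(axis=1, ddof=1)
        sd[sd == 0] = np.nan
        mez = me - me.mean()
        out[m] = (z @ mez) / (sd * me.std(ddof=1) * (len(me) - 1))
    return pd.DataFrame(out)


class ModuleDetector(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper for the full network -> modules path.

    ``fit(X)`` accepts an :class:`ExpressionMatrix` or a genes x strains
    array; the soft threshold is scanned automatically when ``power`` is None.

    Fitted attributes: ``labels_`` (module label per gene), ``power_``,
    ``scan_``, ``modules_`` (the :class:`ModuleSet`).
    """

    def __init__(self, power: int | None = None, rsq_target: float = 0.8,
                 min_module_size: int = 30, cut_height_frac: float = 0.99,
                 signed: bool = False,
                 candidate_powers: tuple[int, ...] = tuple(range(1, 21))):
        self.power = power
        self.rsq_target = rsq_target
        self.min_module_size = min_module_size
        self.cut_height_frac = cut_height_frac
        self.signed = signed
        self.candidate_powers = candidate_powers

    def _params(self) -> NetworkParams:
        return NetworkParams(
            candidate_powers=tuple(self.candidate_powers),
            rsq_target=self.rsq_target,
            signed=self.signed,
            min_module_size=self.min_module_size,
            cut_height_frac=self.cut_height_frac,
        )

    def fit(self, X, y=None):
        if isinstance(X, ExpressionMatrix):
            expr = X
        else:
            arr = np.asarray(X, dtype=float)
            expr = ExpressionMatrix(pd.DataFrame(
                arr,
                index=[f"g{i}" for i in range(arr.shape[0])],
                columns=[f"s{j}" for j in range(arr.shape[1])],
            ))
        params = self._params()
        if self.power is None:
            self.scan_ = scan_powers(expr, params)
            self.power_ = pick_power(self.scan_, params)
        else:
            self.scan_ = None
            self.power_ = int(self.power)
        adj = adjacency(expr, self.power_, signed=self.signed)
        t = tom(adj)
        self.modules_ = detect_modules(t, expr, params, adj=adj)
        self.labels_ = self.modules_.assignment.labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
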