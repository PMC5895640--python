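"""Highly variable gene selection.

Per condition, each gene's coefficient of variation (CV = sd/mean on the log2
scale) is computed across strains; the CV distribution is decomposed into two
normal components by EM; genes with posterior responsibility for the
higher-mean ("variable") component above a cutoff AND mean expression at or
above the floor (default 8 log2 units) are kept, then per-condition selections
are merged by union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .datamodel import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CVProfile:
    """Per-gene mean, sd (n-1 denominator) and cv, pairwise-complete."""

    table: pd.DataFrame  # columns: mean, sd, cv, n; index: gene
    condition: str = "combined"


@dataclass
class MixtureFit:
    weights: np.ndarray  # (2,), sums to 1
    means: np.ndarray  # (2,), means[1] >= means[0]
    sds: np.ndarray  # (2,), > 0
    responsibility: np.ndarray  # P(component 2 | cv) per input value
    log_likelihoods: list[float]
    converged: bool

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihoods)


@dataclass
class VariableGeneSet:
    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    resp_cutoff: float = 0.5
    mean_floor: float = 8.0

    def __len__(self) -> int:
        return len(self.genes)


def compute_cv(expr: ExpressionMatrix, min_n: int = 3) -> CVProfile:
    """CV per gene across strains; genes with < ``min_n`` values or mean <= 0
    get a missing cv (flagged unusable)."""
    data = expr.data
    n = data.notna().sum(axis=1)
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    cv = sd / mean
    bad_mean = mean <= 0
    if bad_mean.any():
        log.warning("%d gene(s) with mean <= 0; cv recorded missing", bad_mean.sum())
    cv[bad_mean | (n < min_n)] = np.nan
    table = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv, "n": n})
    return CVProfile(table, condition=expr.condition)


class CVMixture(BaseEstimator):
    """Two-component Gaussian EM for the CV distribution.

    Initialization splits the data at the median; EM iterates until the
    log-likelihood gain drops below ``tol``.  Components are relabeled so
    component 2 has the larger mean.  A degenerate component (sd -> 0)
    triggers a jittered restart, up to ``max_restarts`` times.

    Fitted attributes: ``weights_``, ``means_``, ``sds_``,
    ``log_likelihoods_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500,
                 max_restarts: int = 5, random_state: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.max_restarts = max_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 10:
            raise ValueError("need >= 10 finite values to fit the CV mixture")
        rng = np.random.default_rng(self.random_state)
        last_err: Exception | None = None
        for attempt in range(self.max_restarts + 1):
            try:
                w, mu, sd, lls, conv = self._em(x, rng, jitter=attempt > 0)
                break
            except _Degenerate as err:
                last_err = err
        else:
            raise RuntimeError(
                f"EM degenerate after {self.max_restarts} restarts: {last_err}"
            )
        order = np.argsort(mu)
        self.weights_, self.means_, self.sds_ = w[order], mu[order], sd[order]
        self.log_likelihoods_ = lls
        self.converged_ = conv
        return self

    def _em(self, x, rng, jitter: bool):
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0:  # all values at/below the median (e.g. constant data)
            raise _Degenerate("no spread around the median")
        mu = np.array([lo.mean(), hi.mean()])
        sd = np.array([max(lo.std(), 1e-6), max(hi.std(), 1e-6)])
        w = np.array([0.5, 0.5])
        if jitter:
            mu = mu + rng.normal(0, max(x.std(), 1e-6) * 0.1, 2)
            sd = sd * rng.uniform(0.5, 2.0, 2)
        floor = max(x.std(), 1e-12) * 1e-6
        lls: list[float] = []
        prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            dens = w * norm.pdf(x[:, None], mu, sd)
            tot = dens.sum(axis=1)
            if np.any(tot <= 0) or not np.all(np.isfinite(tot)):
                raise _Degenerate("vanishing mixture density")
            ll = float(np.log(tot).sum())
            lls.append(ll)
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                raise _Degenerate("empty component")
            w = nk / x.size
            mu = (resp * x[:, None]).sum(axis=0) / nk
            sd = np.sqrt((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
            if np.any(sd < floor):
                raise _Degenerate("component sd collapsed")
            if ll - prev < self.tol and np.isfinite(prev):
                converged = True
                break
            prev = ll
        return w, mu, sd, lls, converged

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibility of the higher-mean component (NaN in -> NaN out)."""
        x = np.asarray(X, dtype=float).ravel()
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        dens = self.weights_ * norm.pdf(x[ok, None], self.means_, self.sds_)
        out[ok] = dens[:, 1] / dens.sum(axis=1)
        return out

    def crossing_point(self) -> float:
        """CV value where the two weighted component densities cross
        (between the two means); alternative decision boundary."""
        from scipy.optimize import brentq

        lo, hi = self.means_

        def diff(v):
            d = self.weights_ * norm.pdf(v, self.means_, self.sds_)
            return d[1] - d[0]

        if lo == hi:
            return lo
        return float(brentq(diff, lo, hi))


class _Degenerate(RuntimeError):
    pass


def fit_cv_mixture(cvs, seed: int = 0, tol: float = 1e-8,
                   max_iter: int = 500) -> MixtureFit:
    """Functional wrapper around :class:`CVMixture`."""
    est = CVMixture(tol=tol, max_iter=max_iter, random_state=seed).fit(cvs)
    return MixtureFit(
        weights=est.weights_,
        means=est.means_,
        sds=est.sds_,
        responsibility=est.predict_proba(cvs),
        log_likelihoods=est.log_likelihoods_,
        converged=est.converged_,
    )


def select_variable_genes(
    profile: CVProfile,
    fit: MixtureFit,
    expr: ExpressionMatrix,
    mean_floor: float = 8.0,
    resp_cutoff: float = 0.5,
) -> VariableGeneSet:
    """Genes with right-component responsibility > cutoff AND mean >= floor."""
    resp = pd.Series(fit.responsibility, index=profile.table.index)
    mean = profile.table["mean"]
    keep = (resp > resp_cutoff) & (mean >= mean_floor)
    genes = set(profile.table.index[keep.fillna(False)])
    return VariableGeneSet(
        genes,
        provenance={expr.condition: set(genes)},
        resp_cutoff=resp_cutoff,
        mean_floor=mean_floor,
    )


def merge_conditions(sets: list[VariableGeneSet]) -> VariableGeneSet:
    """Union of per-condition selections, provenance preserved."""
    if not sets:
        raise ValueError("need at least one VariableGeneSet")
    genes: set[str] = set()
    prov: dict[str, set[str]] = {}
    for s in sets:
        genes |= s.genes
        for cond, g in s.provenance.items():
            prov.setdefault(cond, set()).update(g)
    return VariableGeneSet(genes, provenance=prov,
                           resp_cutoff=sets[0].resp_cutoff,
                           mean_floor=sets[0].mean_floor)


def select_for_conditions(
    exprs: dict[str, ExpressionMatrix],
    mean_floor: float = 8.0,
    resp_cutoff: float = 0.5,
    seed: int = 0,
) -> tuple[VariableGeneSet, dict[str, MixtureFit], dict[str, CVProfile]]:
    """Per-condition CV -> mixture -> selection, merged by union."""
    sets, fits, profiles = [], {}, {}
    for cond, expr in exprs.items():
        prof = compute_cv(expr)
        fit = fit_cv_mixture(prof.table["cv"].to_numpy(), seed=seed)
        sets.append(select_variable_genes(prof, fit, expr, mean_floor, resp_cutoff))
        fits[cond] = fit
        profiles[cond] = prof
    return merge_conditions(sets), fits, profiles
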