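"""Module-level statistics.

Condition profiles ``E_ij`` (module-average expression of strain i under
condition j), one-way ANOVA across conditions (E_ij = mu + T_i + eps_ij),
classification of the four condition patterns, module eigengene vs trait
Pearson correlation, and 2x2 Fisher over-representation against gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CONDITIONS,
    GREY,
    ExpressionMatrix,
    GeneSetCollection,
    ModuleAssignment,
    PhenotypeTable,
)

log = logging.getLogger(__name__)

PATTERN_NAMES = {
    1: "NOE Up -> RSE Restore",
    2: "NOE Down -> RSE Rescue",
    3: "RSS, NOE Up -> RSE Amplify",
    4: "RSS Up -> NOE, RSE Reduce",
}


@dataclass
class PatternSummary:
    table: pd.DataFrame  # module x [mean_<cond>..., pattern, F, p]
    profiles: dict[str, pd.DataFrame]  # module -> strain x condition E_ij


def module_condition_profile(
    exprs: dict[str, ExpressionMatrix], assignment: ModuleAssignment
) -> dict[str, pd.DataFrame]:
    """E_ij table (strain x condition) per non-grey module."""
    out: dict[str, pd.DataFrame] = {}
    for m in assignment.modules():
        members = sorted(assignment.members(m))
        cols = {}
        for cond, expr in exprs.items():
            present = [g for g in members if g in expr.data.index]
            if not present:
                log.warning("module %s has no genes in condition %s", m, cond)
                continue
            cols[cond] = expr.data.loc[present].mean(axis=0)
        out[m] = pd.DataFrame(cols)
    return out


def anova_pattern(e_table: pd.DataFrame | list) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over conditions (columns of E_ij).

    Accepts the strain x condition table or a list of per-group arrays.
    Returns (F, p) with F = MS_between / MS_within and p from
    F(c - 1, N - c).
    """
    if isinstance(e_table, pd.DataFrame):
        groups = [e_table[c].dropna().to_numpy() for c in e_table.columns]
    else:
        groups = [np.asarray(g, dtype=float) for g in e_table]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 conditions with >= 2 strains each")
    if all(np.ptp(g) == 0 for g in groups):
        if len({g[0] for g in groups}) > 1:
            log.warning("zero within-group variance; p at the 0 boundary")
            return np.inf, 0.0
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def classify_pattern(
    condition_means: dict[str, float], delta_min: float = 0.1
) -> int | str:
    """Assign one of the four condition patterns from the four means.

    Deltas are taken against NOS; a condition is called up/down when its
    delta reaches ``delta_min`` with that sign.  Returns 1..4 or
    "unclassified" (also when several patterns match).
    """
    missing = [c for c in CONDITIONS if c not in condition_means]
    if missing:
        raise ValueError(f"missing condition mean(s): {missing}")
    d = {c: condition_means[c] - condition_means["NOS"] for c in CONDITIONS}

    def up(c):
        return d[c] >= delta_min

    def down(c):
        return d[c] <= -delta_min

    def flat(c):
        return abs(d[c]) < delta_min

    matches = []
    if up("NOE") and flat("RSE"):
        matches.append(1)
    if down("NOE") and flat("RSE"):
        matches.append(2)
    if up("RSS") and up("NOE") and up("RSE") and d["RSE"] > max(d["RSS"], d["NOE"]):
        matches.append(3)
    if up("RSS") and (down("NOE") or flat("NOE")) and (down("RSE") or flat("RSE")):
        matches.append(4)
    return matches[0] if len(matches) == 1 else "unclassified"


def summarize_patterns(
    exprs: dict[str, ExpressionMatrix],
    assignment: ModuleAssignment,
    delta_min: float = 0.1,
) -> PatternSummary:
    """Per module: condition means, pattern label, ANOVA F and p."""
    profiles = module_condition_profile(exprs, assignment)
    rows = []
    for m, prof in profiles.items():
        means = prof.mean(axis=0).to_dict()
        row = {"module": m}
        row.update({f"mean_{c}": means.get(c, np.nan) for c in CONDITIONS})
        if all(c in means for c in CONDITIONS):
            row["pattern"] = classify_pattern(means, delta_min)
        else:
            row["pattern"] = "unclassified"
        f, p = anova_pattern(prof)
        row["F"], row["p"] = f, p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("module")
    return PatternSummary(table, profiles)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    phenotypes: PhenotypeTable,
    display_p: float = 0.1,
    min_shared: int = 4,
) -> pd.DataFrame:
    """Pearson r and two-sided t-test p per module x trait pair.

    Long-format output with columns r, p, n and a ``display`` mask at
    ``|p| < display_p`` (the heat-map display rule).
    """
    rows = []
    for m in eigengenes.index:
        me = eigengenes.loc[m]
        for trait in phenotypes.traits:
            y = phenotypes.data[trait]
            shared = me.index.intersection(y.index)
            pair = pd.DataFrame({"me": me[shared], "y": y[shared]}).dropna()
            n = len(pair)
            if n < min_shared:
                log.warning("module %s x %s: only %d shared strains", m, trait, n)
                rows.append({"module": m, "trait": trait, "r": np.nan,
                             "p": np.nan, "n": n, "display": False})
                continue
            r = float(np.corrcoef(pair["me"], pair["y"])[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = float(2 * stats.t.sf(abs(t), df=n - 2))
            rows.append({"module": m, "trait": trait, "r": r, "p": p,
                         "n": n, "display": p < display_p})
    return pd.DataFrame(rows)


def fisher_2x2(in_both: int, a_only: int, b_only: int, neither: int,
               alternative: str = "two-sided") -> tuple[float, float]:
    """(odds ratio, p) for the 2x2 table via Fisher's exact test."""
    table = [[in_both, a_only], [b_only, neither]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def enrichment_fisher(
    module_genes: set[str],
    set_genes: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> dict:
    """Over-representation of a gene set in a module within a universe.

    2x2 cells: genes in both; in module only; in set only; in neither.
    Two-sided p is the headline number; the one-sided (greater) p is also
    reported since over-representation is directional.
    """
    if not universe:
        raise ValueError("empty universe")
    mod = module_genes & universe
    gs = set_genes & universe
    in_both = len(mod & gs)
    a_only = len(mod - gs)
    b_only = len(gs - mod)
    neither = len(universe) - in_both - a_only - b_only
    odds, p_two = fisher_2x2(in_both, a_only, b_only, neither, "two-sided")
    _, p_greater = fisher_2x2(in_both, a_only, b_only, neither, "greater")
    return {
        "in_both": in_both, "module_only": a_only, "set_only": b_only,
        "neither": neither, "odds_ratio": odds, "p": p_two,
        "p_greater": p_greater, "significant": p_two < alpha,
    }


def enrichment_table(
    assignment: ModuleAssignment,
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of every gene set in every non-grey module.

    The default universe is the set of genes entering the network (the
    assignment's genes, grey included as background)."""
    universe = universe if universe is not None else set(assignment.genes)
    rows = []
    for m in assignment.modules():
        members = assignment.members(m)
        for name in collection.names():
            res = enrichment_fisher(members, collection[name], universe, alpha)
            rows.append({"module": m, "gene_set": name, **res})
    df = pd.DataFrame(rows)
    if len(df):
        # optional BH-adjusted column alongside the raw p the thresholds use
        p = df["p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.clip(adj, 0, 1)
        df["p_bh"] = out
    return df
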