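"""Cross-condition module preservation and specificity.

Preservation of a module between two conditions is measured by the number of
shared genes between module pairs and a Fisher exact test on the 2x2 overlap
table in the shared gene universe (p < 0.01 threshold).  A module is
condition-specific when it has no significantly overlapping counterpart in
any module of every comparison condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ModuleAssignment


@dataclass
class OverlapMatrix:
    """Long-format overlap rows between two conditions' partitions."""

    condition_a: str
    condition_b: str
    table: pd.DataFrame  # module_a, module_b, n_a, n_b, shared, p, p_two, significant
    universe_size: int


@dataclass
class SpecificityCall:
    module: str
    condition: str
    comparisons: list[str]
    specific: bool
    best_p: float  # smallest overlap p against any comparison module


def module_overlap(
    part_a: ModuleAssignment,
    part_b: ModuleAssignment,
    universe: set[str] | None = None,
    alpha: float = 0.01,
    condition_a: str = "A",
    condition_b: str = "B",
) -> OverlapMatrix:
    """Fisher overlap p for every non-grey module pair.

    The universe defaults to the intersection of the two partitions' gene
    sets (the conservative choice for Fisher validity); both one-sided
    (over-representation, used for the significance call) and two-sided
    p-values are reported.
    """
    genes_a, genes_b = set(part_a.genes), set(part_b.genes)
    if universe is None:
        universe = genes_a & genes_b
    if not universe:
        raise ValueError("partitions share no genes (disjoint universes)")
    n_u = len(universe)
    rows = []
    for ma in part_a.modules():
        set_a = part_a.members(ma) & universe
        for mb in part_b.modules():
            set_b = part_b.members(mb) & universe
            shared = len(set_a & set_b)
            n_a, n_b = len(set_a), len(set_b)
            # hypergeometric upper tail == one-sided Fisher "greater"
            p_one = float(stats.hypergeom.sf(shared - 1, n_u, n_a, n_b))
            table = [[shared, n_a - shared], [n_b - shared, n_u - n_a - n_b + shared]]
            _, p_two = stats.fisher_exact(table, alternative="two-sided")
            rows.append({
                "module_a": ma, "module_b": mb, "n_a": n_a, "n_b": n_b,
                "shared": shared, "p": p_one, "p_two": float(p_two),
                "significant": p_one < alpha,
            })
    return OverlapMatrix(condition_a, condition_b, pd.DataFrame(rows), n_u)


def preserved_module_count(overlap: OverlapMatrix) -> dict[str, int]:
    """Modules of condition A with >= 1 significant counterpart in B, under
    both counting conventions (once per best match vs per any match)."""
    tab = overlap.table
    sig = tab[tab["significant"]]
    return {
        "preserved_modules": int(sig["module_a"].nunique()),
        "significant_pairs": int(len(sig)),
    }


def call_specific_modules(
    overlaps: list[OverlapMatrix],
) -> list[SpecificityCall]:
    """Specificity of condition-A modules against all comparison conditions.

    All overlap matrices must share the same condition A.  A module is
    specific iff it has no significant overlap in any comparison.
    """
    if not overlaps:
        return []
    cond = overlaps[0].condition_a
    if any(o.condition_a != cond for o in overlaps):
        raise ValueError("all overlap matrices must share condition A")
    modules = sorted(set().union(*(set(o.table["module_a"]) for o in overlaps)))
    calls = []
    for m in modules:
        best_p = 1.0
        significant_somewhere = False
        for o in overlaps:
            rows = o.table[o.table["module_a"] == m]
            if len(rows):
                best_p = min(best_p, float(rows["p"].min()))
                if rows["significant"].any():
                    significant_somewhere = True
        calls.append(SpecificityCall(
            module=m,
            condition=cond,
            comparisons=[o.condition_b for o in overlaps],
            specific=not significant_somewhere,
            best_p=best_p,
        ))
    return calls


def neg_log10_matrix(overlap: OverlapMatrix) -> pd.DataFrame:
    """Heat-map-ready matrix of -log10 overlap p (modules A x modules B)."""
    tab = overlap.table
    mat = tab.pivot(index="module_a", columns="module_b", values="p")
    return -np.log10(mat.clip(lower=np.finfo(float).tiny))
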