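"""Core data containers for the strain-panel network pipeline.

All tabular containers wrap :class:`pandas.DataFrame` / :class:`pandas.Series`
and validate their invariants on construction.  Expression values are log2
intensities; genotype codes are 0 (B6-like allele), 1 (D2-like allele) or
missing (NaN); PPI scores are STRING-style integers in [0, 1000].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("NOS", "RSS", "NOE", "RSE")
#: Label for genes not assigned to any co-expression module.
GREY = "grey"


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise DataModelError(f"duplicate {what} identifier(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2 strain-mean expression, genes x strains, tagged with a condition.

    Parameters
    ----------
    data : DataFrame
        Genes in the index, strains in the columns, float values (NaN for
        missing cells).
    condition : str
        One of NOS/RSS/NOE/RSE or "combined".
    """

    data: pd.DataFrame
    condition: str = "combined"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "strain")
        if self.data.shape[0] < 2:
            raise DataModelError("expression matrix needs >= 2 genes")
        if self.data.shape[1] < 3:
            raise DataModelError("expression matrix needs >= 3 strains")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataModelError("expression values must be numeric")
        if np.isinf(vals).any():
            raise DataModelError("expression values must be finite or NaN")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def strains(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def zscore(self) -> "ExpressionMatrix":
        """Per-gene z-score across strains (optional post-log2 scaling)."""
        v = self.data
        out = v.sub(v.mean(axis=1), axis=0).div(v.std(axis=1, ddof=1), axis=0)
        return ExpressionMatrix(out, condition=self.condition)


@dataclass
class GenotypeMatrix:
    """Biallelic RI genotypes: markers x strains plus a marker map.

    ``codes`` holds 0/1/NaN; ``marker_map`` has columns ``chrom`` and ``pos``
    (unit recorded in ``pos_unit``, "cM" by default).  Positions must be
    non-decreasing within each chromosome.
    """

    codes: pd.DataFrame
    marker_map: pd.DataFrame
    pos_unit: str = "cM"

    def __post_init__(self) -> None:
        _check_unique(self.codes.index, "marker")
        _check_unique(self.codes.columns, "strain")
        if not self.codes.index.equals(self.marker_map.index):
            raise DataModelError("codes and marker_map must share the marker index")
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise DataModelError(f"genotype codes outside {{0,1,missing}}: {bad[:5]}")
        self.codes = self.codes.astype(float)
        self.codes.index.name = None
        self.codes.columns.name = None
        self.marker_map.index.name = None
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise DataModelError(
                    f"marker positions decrease within chromosome {chrom!r}"
                )

    @property
    def markers(self) -> list[str]:
        return list(self.codes.index)

    @property
    def strains(self) -> list[str]:
        return list(self.codes.columns)


@dataclass
class PhenotypeTable:
    """Strains x named behavioural traits (real-valued, NaN for missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "strain")
        _check_unique(self.data.columns, "trait")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def usable_traits(self, min_n: int = 3) -> list[str]:
        """Traits with at least ``min_n`` non-missing strain values."""
        n = self.data.notna().sum(axis=0)
        return list(n.index[n >= min_n])


@dataclass
class PPIEdgeList:
    """Scored protein-interaction edges (STRING protein-links style).

    Self-edges are rejected; duplicate unordered pairs are collapsed keeping
    the maximum score.  Scores are integers in [0, 1000].
    """

    edges: pd.DataFrame  # columns: protein1, protein2, score

    def __post_init__(self) -> None:
        df = self.edges.copy()
        required = ["protein1", "protein2", "score"]
        if list(df.columns[:3]) != required:
            df.columns = required + list(df.columns[3:])
        if (df["protein1"] == df["protein2"]).any():
            raise DataModelError("self-edges are not allowed in a PPI edge list")
        sc = df["score"].to_numpy()
        if len(sc) and (sc.min() < 0 or sc.max() > 1000):
            raise DataModelError("PPI scores must lie in [0, 1000]")
        # canonical unordered orientation, then collapse duplicates on max score
        a = df["protein1"].astype(str)
        b = df["protein2"].astype(str)
        lo = a.where(a <= b, b)
        hi = b.where(a <= b, a)
        df = pd.DataFrame({"protein1": lo, "protein2": hi, "score": df["score"].astype(int)})
        df = (
            df.groupby(["protein1", "protein2"], as_index=False)["score"]
            .max()
            .sort_values(["protein1", "protein2"])
            .reset_index(drop=True)
        )
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def proteins(self) -> set[str]:
        return set(self.edges["protein1"]) | set(self.edges["protein2"])


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataModelError(f"gene set {name!r} is empty")
            self.sets[name] = set(map(str, members))
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclass
class ModuleAssignment:
    """Gene -> module label partition; label ``grey`` marks unassigned genes."""

    labels: pd.Series  # index: gene, value: module label (str)

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "gene")
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    def modules(self, include_grey: bool = False) -> list[str]:
        """Module labels ordered by decreasing size (ties broken by label)."""
        counts = self.labels.value_counts()
        labs = [m for m in counts.index if include_grey or m != GREY]
        return sorted(labs, key=lambda m: (-counts[m], m))

    def members(self, module: str) -> set[str]:
        return set(self.labels.index[self.labels == module])

    def size(self, module: str) -> int:
        return int((self.labels == module).sum())
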