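import numpy as np
import pandas as pd
import pytest

from bxdnet import SyntheticDesign, simulate
from bxdnet.datamodel import ExpressionMatrix
from bxdnet.simulate import CausalTriplet, ModuleSpec


@pytest.fixture(scope="session")
def dataset():
    """Default-design synthetic dataset (41 strains, 3000 genes)."""
    return simulate(seed=1)


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down design for fast end-to-end tests."""
    return SyntheticDesign(
        n_strains=30,
        n_genes=400,
        n_markers=20,
        marker_spacing_cm=20.0,
        modules=[
            ModuleSpec(60, 1), ModuleSpec(50, 2),
            ModuleSpec(40, 3), ModuleSpec(30, 4),
        ],
        causal_triplets=[CausalTriplet(5, 0, "TRAIT1", model=1)],
        ppi_n_random_edges=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate(small_design)


def combined_matrix(exprs, genes):
    """Condition matrices column-concatenated with condition-tagged strains."""
    parts = []
    for cond, e in exprs.items():
        sub = e.data.reindex(genes)
        sub.columns = [f"{cond}:{s}" for s in sub.columns]
        parts.append(sub)
    return ExpressionMatrix(pd.concat(parts, axis=1), condition="combined")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
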