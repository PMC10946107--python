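from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qnetdiff import CountTable, FixtureSpec, Taxonomy, WeightedNetwork
from qnetdiff.synthetic import generate_fixture

#: Small fixture spec used by pipeline-level tests: same planted structure
#: as the default study conditions, fewer taxa so each run stays fast.
SMALL_SPEC = FixtureSpec(n_taxa=24, n_samples=40, seed=7)

#: A null spec: no planted blocks, no fold change, no siblings.
NULL_SPEC = FixtureSpec(
    n_taxa=20,
    n_samples=200,
    fold_change=1.0,
    n_rewiring_partners=0,
    n_differential=0,
    sibling_set_sizes=(),
)


def make_count_table(matrix, group="X", taxa=None, samples=None) -> CountTable:
    matrix = np.asarray(matrix)
    taxa = taxa or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{k}" for k in range(matrix.shape[1])]
    return CountTable(group, pd.DataFrame(matrix, index=taxa, columns=samples))


def random_weight_matrix(rng, n, density=0.3, low=0.4, high=1.0) -> np.ndarray:
    """Random symmetric non-negative weights; nonzero entries in (low, high]."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = low + (high - low) * rng.random(len(iu[0]))
    w[iu] = np.where(mask, vals, 0.0)
    return w + w.T


def random_network_pair(rng, n, **kw) -> tuple[WeightedNetwork, WeightedNetwork]:
    taxa = [f"t{i}" for i in range(n)]
    return (
        WeightedNetwork(taxa, random_weight_matrix(rng, n, **kw)),
        WeightedNetwork(taxa, random_weight_matrix(rng, n, **kw)),
    )


@pytest.fixture(scope="session")
def small_fixture():
    """One generated small fixture shared across pipeline tests."""
    return generate_fixture(SMALL_SPEC)


@pytest.fixture
def flat_taxonomy():
    """Taxonomy giving every queried taxon its own parent-level category."""

    class _Flat(Taxonomy):
        def __init__(self):
            super().__init__({})

        def sup_category(self, taxon):
            return f"fam_{taxon}"

        def require(self, taxa):
            return None

    return _Flat()
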