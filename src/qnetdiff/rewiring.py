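"""Core subnetworks and the per-node rewiring index (QNetDiff score).

After contraction and core selection, both networks are restricted to the
core taxa plus every taxon adjacent to a core taxon in at least one network,
giving a pair G_X = (V, E_X), G_Y = (V, E_Y) over a shared node set V.

For unweighted graphs the natural measure of how much a node rewired is the
cardinality of the symmetric difference of its neighbour sets.  The QNetDiff
score extends this to edge weights via weighted union and intersection:

    A_{X∩Y}[v] = Σ_w min(A_X[v,w], A_Y[v,w])
    A_{X∪Y}[v] = Σ_w max(A_X[v,w], A_Y[v,w])
    QNetDiff[v] = A_{X∪Y}[v] − A_{X∩Y}[v]

with the sum over the union neighbourhood of v (absent edges weigh 0, so
summing over all of V is equivalent).  The score is non-negative, symmetric
in the two networks, and zero exactly when v's weighted rows agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_selection import CoreSet
from .network import WeightedNetwork
from .tables_io import AbundanceTable

__all__ = [
    "SubnetworkPair",
    "build_core_subnetworks",
    "qnetdiff_scores",
    "feature_table",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = [
    "taxon",
    "qnetdiff",
    "degree_X",
    "degree_Y",
    "mean_abund_X",
    "mean_abund_Y",
    "p_value",
    "is_core",
]

_SYM_TOL = 1e-9


@dataclass
class SubnetworkPair:
    """The networks G_X and G_Y restricted to a shared node list V."""

    taxa: list[str]
    a_x: np.ndarray
    a_y: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        n = len(self.taxa)
        self.a_x = np.asarray(self.a_x, dtype=float)
        self.a_y = np.asarray(self.a_y, dtype=float)
        for name, a in (("A_X", self.a_x), ("A_Y", self.a_y)):
            if a.shape != (n, n):
                raise ValueError(f"{name} shape {a.shape} does not match {n} nodes")
            if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
                raise ValueError(f"{name} is not symmetric")

    @property
    def net_x(self) -> WeightedNetwork:
        return WeightedNetwork(self.taxa, self.a_x)

    @property
    def net_y(self) -> WeightedNetwork:
        return WeightedNetwork(self.taxa, self.a_y)


def build_core_subnetworks(
    net_x: WeightedNetwork, net_y: WeightedNetwork, core: CoreSet
) -> SubnetworkPair:
    """Restrict both networks to core taxa and their neighbours.

    V = core ∪ {w : w adjacent to a core taxon in net_x or net_y}; each
    network keeps exactly the edges with both endpoints in V.  An empty core
    set yields an empty pair.
    """
    if net_x.taxa != net_y.taxa:
        raise ValueError("networks must share an identical ordered node list")
    missing = [t for t in core.core if t not in net_x.taxa]
    if missing:
        raise ValueError(f"core taxa not present in the networks: {missing}")
    pos = {t: i for i, t in enumerate(net_x.taxa)}
    in_v = np.zeros(net_x.n_nodes, dtype=bool)
    for t in core.core:
        i = pos[t]
        in_v[i] = True
        in_v |= net_x.weights[i] > 0
        in_v |= net_y.weights[i] > 0
    taxa = [t for t, k in zip(net_x.taxa, in_v) if k]
    idx = np.flatnonzero(in_v)
    return SubnetworkPair(
        taxa=taxa,
        a_x=net_x.weights[np.ix_(idx, idx)],
        a_y=net_y.weights[np.ix_(idx, idx)],
    )


def qnetdiff_scores(pair: SubnetworkPair) -> pd.Series:
    """Per-node rewiring index: weighted union minus weighted intersection."""
    inter = np.minimum(pair.a_x, pair.a_y).sum(axis=1)
    union = np.maximum(pair.a_x, pair.a_y).sum(axis=1)
    return pd.Series(union - inter, index=pair.taxa, name="qnetdiff")


def feature_table(
    pair: SubnetworkPair,
    at_x: AbundanceTable,
    at_y: AbundanceTable,
    p_values: Mapping[str, float],
    core: CoreSet,
) -> pd.DataFrame:
    """Assemble the per-node output table, sorted by score (descending).

    Each node of the contracted networks is a representative taxon, so its
    abundance row and p-value are its own.  A p-value genuinely unavailable
    for a node is recorded as missing (NaN) rather than raised.
    """
    scores = qnetdiff_scores(pair)
    deg_x = (pair.a_x > 0).sum(axis=1)
    deg_y = (pair.a_y > 0).sum(axis=1)
    rows = []
    for i, taxon in enumerate(pair.taxa):
        rows.append(
            {
                "taxon": taxon,
                "qnetdiff": float(scores.iloc[i]),
                "degree_X": int(deg_x[i]),
                "degree_Y": int(deg_y[i]),
                "mean_abund_X": float(at_x.row(taxon).mean()),
                "mean_abund_Y": float(at_y.row(taxon).mean()),
                "p_value": float(p_values[taxon]) if taxon in p_values else np.nan,
                "is_core": taxon in core.core,
            }
        )
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    df = df.sort_values(
        ["qnetdiff", "taxon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
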