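"""Weighted co-occurrence networks over an ordered taxon list.

A :class:`WeightedNetwork` is a symmetric non-negative weight matrix indexed
by an ordered list of taxon names.  A weight of 0 means "no edge"; the
diagonal is always 0.  All network-valued stages of the pipeline (thresholded
correlation networks, contracted networks, core subnetworks) use this type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = ["WeightedNetwork", "difference_network"]

_SYM_TOL = 1e-9


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency over an ordered taxon list.

    Parameters
    ----------
    taxa
        Ordered node labels; must be unique.
    weights
        Square ``(n, n)`` array of non-negative edge weights.  Entry 0 means
        no edge.  Symmetrised and diagonal-zeroed on construction; asymmetry
        beyond 1e-9 is an error.
    """

    taxa: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.taxa)
        if w.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {w.shape} does not match {n} taxa"
            )
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon names in network node list")
        if not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("weight matrix is not symmetric")
        if np.any(w < 0):
            raise ValueError("negative edge weights are not allowed")
        w = (w + w.T) / 2.0  # exact symmetry
        np.fill_diagonal(w, 0.0)
        self.weights = w

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(np.triu(self.weights, k=1).sum())

    def degrees(self) -> np.ndarray:
        """Number of incident edges (nonzero weights) per node."""
        return (self.weights > 0).sum(axis=1)

    def index_of(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in network") from None

    # -- derived networks -------------------------------------------------

    def subnetwork(self, taxa: Sequence[str]) -> "WeightedNetwork":
        """Induced subnetwork on ``taxa`` (order as given)."""
        idx = [self.index_of(t) for t in taxa]
        return WeightedNetwork(list(taxa), self.weights[np.ix_(idx, idx)])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.taxa)
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(iu, ju):
            g.add_edge(self.taxa[i], self.taxa[j], weight=float(self.weights[i, j]))
        return g

    # -- I/O ---------------------------------------------------------------

    def write_edgelist(self, path: str | Path) -> None:
        """Write a weighted edge-list TSV with header ``u v weight``."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("u\tv\tweight\n")
            iu, ju = np.nonzero(np.triu(self.weights, k=1))
            for i, j in zip(iu, ju):
                fh.write(
                    f"{self.taxa[i]}\t{self.taxa[j]}\t{self.weights[i, j]:.10g}\n"
                )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def difference_network(a: WeightedNetwork, b: WeightedNetwork) -> WeightedNetwork:
    """Element-wise ``|A - B|`` network over a shared node list.

    The row sums of this network equal the per-node rewiring scores, which is
    what makes it a useful visual companion to the score table.
    """
    if a.taxa != b.taxa:
        raise ValueError("networks must share an identical ordered node list")
    return WeightedNetwork(a.taxa, np.abs(a.weights - b.weights))
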