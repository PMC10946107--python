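"""Taxonomy-constrained node contraction (false-correlation removal).

Multi-mapped reads split among closely related taxa make those taxa's count
profiles nearly identical, which produces spuriously strong co-occurrence
edges.  To remove them, each group's network is clustered with the Louvain
method, and taxa are unified when (1) they share the parent-level taxonomic
category and (2) they fall in the same cluster in *both* groups' networks.
Each resulting similar-bacteria group is contracted to a single node labelled
by its representative: the member with the highest mean relative abundance
over the pooled samples of both groups.

The contracted edge weight between two groups of taxa is the arithmetic mean
of the *existing* (nonzero) edge weights between their members, or 0 when no
such edge exists; a config switch allows averaging over all member pairs
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .network import WeightedNetwork
from .tables_io import AbundanceTable, Taxonomy

__all__ = [
    "ClusterAssignment",
    "SimilarGroup",
    "ContractionMap",
    "cluster_nodes",
    "find_similar_groups",
    "identity_contraction_map",
    "choose_representatives",
    "contract_networks",
    "write_groups_tsv",
]


@dataclass
class ClusterAssignment:
    """Taxon -> cluster id for one group's network (a total partition)."""

    assignment: dict[str, int]

    def __getitem__(self, taxon: str) -> int:
        return self.assignment[taxon]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class SimilarGroup:
    """A set of taxa unified into one node.

    All members share the parent-level category and the cluster id in both
    groups' networks; the representative (once chosen) is the member with the
    highest pooled mean abundance.
    """

    members: list[str]
    sup_category: str
    representative: str | None = None
    representative_mean_abundance: float | None = None


@dataclass
class ContractionMap:
    """Partition of the effective taxa into similar-bacteria groups."""

    groups: list[SimilarGroup]
    _by_taxon: dict[str, SimilarGroup] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_taxon = {}
        for g in self.groups:
            for t in g.members:
                if t in self._by_taxon:
                    raise ValueError(f"taxon {t!r} appears in two groups")
                self._by_taxon[t] = g

    def group_of(self, taxon: str) -> SimilarGroup:
        return self._by_taxon[taxon]

    @property
    def taxa(self) -> list[str]:
        return list(self._by_taxon)

    @property
    def representatives(self) -> list[str]:
        reps = []
        for g in self.groups:
            if g.representative is None:
                raise ValueError("representatives have not been chosen yet")
            reps.append(g.representative)
        return reps

    @property
    def n_multi(self) -> int:
        """Number of groups with two or more members."""
        return sum(len(g.members) >= 2 for g in self.groups)


def cluster_nodes(net: WeightedNetwork, seed: int = 0) -> ClusterAssignment:
    """Louvain community detection on the weighted network, seeded.

    Isolated nodes (a taxon can have edges in only one of the two networks)
    each form their own community.  Cluster ids are canonicalised by sorting
    communities by their lexicographically smallest member, so the labels do
    not depend on internal set ordering.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot cluster an empty network")
    g = net.to_networkx()
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: min(c))
    assignment = {t: i for i, comm in enumerate(communities) for t in comm}
    return ClusterAssignment(assignment)


def find_similar_groups(
    taxonomy: Taxonomy,
    cl_x: ClusterAssignment,
    cl_y: ClusterAssignment,
) -> ContractionMap:
    """Group taxa by (parent-level category, cluster in X, cluster in Y).

    These are the equivalence classes of the triple key, so maximality is
    automatic.  Taxa differing in any component form separate (possibly
    singleton) groups.
    """
    if set(cl_x.assignment) != set(cl_y.assignment):
        raise ValueError("cluster assignments must cover the same taxa")
    taxonomy.require(cl_x.assignment)
    buckets: dict[tuple[str, int, int], list[str]] = {}
    for taxon in cl_x.assignment:
        key = (taxonomy.sup_category(taxon), cl_x[taxon], cl_y[taxon])
        buckets.setdefault(key, []).append(taxon)
    groups = [
        SimilarGroup(members=sorted(members), sup_category=key[0])
        for key, members in sorted(buckets.items())
    ]
    return ContractionMap(groups)


def identity_contraction_map(taxa: list[str], taxonomy: Taxonomy) -> ContractionMap:
    """All-singleton partition: every taxon represents itself.

    Used when contraction is skipped; downstream stages then operate on the
    uncontracted networks unchanged.
    """
    taxonomy.require(taxa)
    return ContractionMap(
        [
            SimilarGroup(
                members=[t],
                sup_category=taxonomy.sup_category(t),
                representative=t,
            )
            for t in taxa
        ]
    )


def choose_representatives(
    cmap: ContractionMap, at_x: AbundanceTable, at_y: AbundanceTable
) -> ContractionMap:
    """Pick each group's member with the highest pooled mean abundance.

    The mean is taken over the concatenated samples of both groups; ties are
    broken lexicographically by taxon name.  Mutates and returns ``cmap``.
    """
    for g in cmap.groups:
        best_name, best_mean = None, -np.inf
        for t in sorted(g.members):
            pooled = np.concatenate([at_x.row(t), at_y.row(t)])
            m = float(pooled.mean())
            if m > best_mean:  # strict: first (lexicographic) wins ties
                best_name, best_mean = t, m
        g.representative = best_name
        g.representative_mean_abundance = best_mean
    return cmap


def contract_networks(
    net: WeightedNetwork, cmap: ContractionMap, mean_mode: str = "edges"
) -> WeightedNetwork:
    """Contract each similar-bacteria group to its representative node.

    The weight between two contracted nodes is the mean over the *existing*
    inter-group edges (``mean_mode="edges"``, the default), or the mean over
    all member pairs counting absent edges as 0 (``mean_mode="all-pairs"``).
    Either way the weight is 0 when no inter-group edge exists.  Within-group
    edges are discarded (zero diagonal).
    """
    if mean_mode not in ("edges", "all-pairs"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    if sorted(cmap.taxa) != sorted(net.taxa):
        raise ValueError("contraction map must partition the network's nodes")
    # order contracted nodes by their representative's position in the input
    pos = {t: i for i, t in enumerate(net.taxa)}
    groups = sorted(cmap.groups, key=lambda g: pos[g.representative])
    member_idx = [np.array([pos[t] for t in g.members]) for g in groups]
    k = len(groups)
    w = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = net.weights[np.ix_(member_idx[a], member_idx[b])]
            nz = block[block > 0]
            if nz.size == 0:
                continue
            if mean_mode == "edges":
                w[a, b] = w[b, a] = float(nz.mean())
            else:
                w[a, b] = w[b, a] = float(block.mean())
    return WeightedNetwork([g.representative for g in groups], w)


def write_groups_tsv(cmap: ContractionMap, path: str | Path) -> None:
    """Write the unified-group listing (members semicolon-joined)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tsup_category\trepresentative\tmembers\n")
        for i, g in enumerate(cmap.groups):
            fh.write(
                f"{i}\t{g.sup_category}\t{g.representative or ''}\t"
                + ";".join(g.members)
                + "\n"
            )
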