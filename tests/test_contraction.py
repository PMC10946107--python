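"""Clustering, similar-group formation, representatives, and contraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qnetdiff import (
    AbundanceTable,
    ClusterAssignment,
    Taxonomy,
    WeightedNetwork,
    choose_representatives,
    cluster_nodes,
    contract_networks,
    find_similar_groups,
    identity_contraction_map,
)
from qnetdiff.contraction import ContractionMap, SimilarGroup, write_groups_tsv


def _net(taxa, edges):
    w = np.zeros((len(taxa), len(taxa)))
    for u, v, x in edges:
        w[taxa.index(u), taxa.index(v)] = w[taxa.index(v), taxa.index(u)] = x
    return WeightedNetwork(taxa, w)


def _abund(values: dict[str, list[float]], group="X") -> AbundanceTable:
    df = pd.DataFrame(values).T
    df.columns = [f"{group}{k}" for k in range(df.shape[1])]
    return AbundanceTable(group, df)


class TestClusterNodes:
    @staticmethod
    def _two_cliques():
        taxa = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        edges = []
        for grp in ("a", "b"):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((f"{grp}{i}", f"{grp}{j}", 0.9))
        edges.append(("a0", "b0", 0.41))  # weak bridge
        return _net(taxa, edges)

    def test_cliques_split_by_modularity(self):
        cl = cluster_nodes(self._two_cliques(), seed=0)
        a_ids = {cl[f"a{i}"] for i in range(4)}
        b_ids = {cl[f"b{i}"] for i in range(4)}
        assert len(a_ids) == len(b_ids) == 1
        assert a_ids != b_ids

    def test_seeded_determinism(self):
        net = self._two_cliques()
        assert cluster_nodes(net, seed=3).assignment == cluster_nodes(net, seed=3).assignment

    def test_partition_covers_all_nodes_including_isolates(self):
        net = _net(["a", "b", "c"], [("a", "b", 0.5)])  # c isolated here
        cl = cluster_nodes(net, seed=0)
        assert set(cl.assignment) == {"a", "b", "c"}


class TestFindSimilarGroups:
    TAX = Taxonomy({"g1": "famA", "g2": "famA", "g3": "famA", "g4": "famB"})

    @staticmethod
    def _cl(d):
        return ClusterAssignment(dict(d))

    def test_shared_family_and_clusters_unify(self):
        cx = self._cl({"g1": 1, "g2": 1, "g3": 1})
        cy = self._cl({"g1": 2, "g2": 2, "g3": 2})
        cmap = find_similar_groups(self.TAX, cx, cy)
        assert len(cmap.groups) == 1
        assert cmap.groups[0].members == ["g1", "g2", "g3"]

    def test_different_cluster_in_one_group_splits(self):
        cx = self._cl({"g1": 1, "g2": 2})
        cy = self._cl({"g1": 1, "g2": 1})
        cmap = find_similar_groups(self.TAX, cx, cy)
        assert sorted(len(g.members) for g in cmap.groups) == [1, 1]

    def test_different_family_splits(self):
        cx = self._cl({"g3": 1, "g4": 1})
        cy = self._cl({"g3": 1, "g4": 1})
        cmap = find_similar_groups(self.TAX, cx, cy)
        assert sorted(len(g.members) for g in cmap.groups) == [1, 1]

    def test_missing_taxonomy_entry_rejected(self):
        cx = self._cl({"zz": 1})
        with pytest.raises(Exception, match="zz"):
            find_similar_groups(self.TAX, cx, cx)

    def test_mismatched_coverage_rejected(self):
        with pytest.raises(ValueError, match="same taxa"):
            find_similar_groups(self.TAX, self._cl({"g1": 1}), self._cl({"g2": 1}))


class TestChooseRepresentatives:
    def test_singleton_represents_itself(self):
        cmap = ContractionMap([SimilarGroup(["a"], "famA")])
        ax = _abund({"a": [0.1, 0.2]})
        ay = _abund({"a": [0.3, 0.4]}, group="Y")
        choose_representatives(cmap, ax, ay)
        assert cmap.groups[0].representative == "a"

    def test_highest_pooled_mean_wins(self):
        cmap = ContractionMap([SimilarGroup(["a", "b"], "famA")])
        ax = _abund({"a": [0.02, 0.02], "b": [0.05, 0.05]})
        ay = _abund({"a": [0.02, 0.02], "b": [0.05, 0.05]}, group="Y")
        choose_representatives(cmap, ax, ay)
        assert cmap.groups[0].representative == "b"
        assert cmap.groups[0].representative_mean_abundance == pytest.approx(0.05)

    def test_representative_mean_is_maximal(self):
        rng = np.random.default_rng(0)
        members = [f"g{i}" for i in range(5)]
        ax = _abund({m: rng.random(4).tolist() for m in members})
        ay = _abund({m: rng.random(4).tolist() for m in members}, group="Y")
        cmap = ContractionMap([SimilarGroup(list(members), "famA")])
        choose_representatives(cmap, ax, ay)
        g = cmap.groups[0]
        rep_mean = np.concatenate([ax.row(g.representative), ay.row(g.representative)]).mean()
        for m in members:
            assert rep_mean >= np.concatenate([ax.row(m), ay.row(m)]).mean()

    def test_tie_broken_lexicographically(self):
        cmap = ContractionMap([SimilarGroup(["b", "a"], "famA")])
        ax = _abund({"a": [0.1, 0.1], "b": [0.1, 0.1]})
        ay = _abund({"a": [0.1, 0.1], "b": [0.1, 0.1]}, group="Y")
        choose_representatives(cmap, ax, ay)
        assert cmap.groups[0].representative == "a"


class TestContractNetworks:
    def _cmap(self):
        return ContractionMap(
            [
                SimilarGroup(["a", "b"], "famA", representative="a"),
                SimilarGroup(["c"], "famC", representative="c"),
            ]
        )

    def test_mean_over_existing_edges_only(self):
        net = _net(["a", "b", "c"], [("a", "c", 0.5)])  # b-c absent
        con = contract_networks(net, self._cmap(), "edges")
        assert con.taxa == ["a", "c"]
        assert con.weights[0, 1] == pytest.approx(0.5)

    def test_all_pairs_mode_averages_in_zeros(self):
        net = _net(["a", "b", "c"], [("a", "c", 0.5)])
        con = contract_networks(net, self._cmap(), "all-pairs")
        assert con.weights[0, 1] == pytest.approx(0.25)

    def test_no_intergroup_edge_gives_zero(self):
        net = _net(["a", "b", "c"], [("a", "b", 0.9)])  # within-group only
        con = contract_networks(net, self._cmap())
        assert con.n_edges == 0

    def test_all_singleton_partition_is_identity(self):
        taxa = ["a", "b", "c"]
        net = _net(taxa, [("a", "b", 0.5), ("b", "c", 0.7)])
        tax = Taxonomy({t: f"fam_{t}" for t in taxa})
        con = contract_networks(net, identity_contraction_map(taxa, tax))
        assert con.taxa == taxa
        np.testing.assert_allclose(con.weights, net.weights)

    def test_member_order_invariance(self):
        net = _net(["a", "b", "c"], [("a", "c", 0.5), ("b", "c", 0.7)])
        fwd = contract_networks(net, self._cmap())
        swapped = ContractionMap(
            [
                SimilarGroup(["b", "a"], "famA", representative="a"),
                SimilarGroup(["c"], "famC", representative="c"),
            ]
        )
        rev = contract_networks(net, swapped)
        assert fwd.taxa == rev.taxa
        np.testing.assert_allclose(fwd.weights, rev.weights)

    def test_contracted_weights_exceed_threshold(self):
        """Mean of supra-threshold weights is itself supra-threshold."""
        rng = np.random.default_rng(2)
        taxa = [f"g{i}" for i in range(9)]
        w = np.zeros((9, 9))
        iu = np.triu_indices(9, k=1)
        mask = rng.random(len(iu[0])) < 0.5
        w[iu] = np.where(mask, rng.uniform(0.4 + 1e-9, 1.0, len(iu[0])), 0.0)
        net = WeightedNetwork(taxa, w + w.T)
        cmap = ContractionMap(
            [
                SimilarGroup(taxa[0:3], "famA", representative=taxa[0]),
                SimilarGroup(taxa[3:6], "famB", representative=taxa[3]),
                SimilarGroup(taxa[6:9], "famC", representative=taxa[6]),
            ]
        )
        con = contract_networks(net, cmap, "edges")
        nz = con.weights[con.weights > 0]
        assert np.all(nz > 0.4)

    def test_partition_must_cover_nodes(self):
        net = _net(["a", "b"], [])
        with pytest.raises(ValueError, match="partition"):
            contract_networks(net, self._cmap())


def test_groups_tsv_roundtrip(tmp_path):
    cmap = ContractionMap(
        [SimilarGroup(["a", "b"], "famA", representative="a"),
         SimilarGroup(["c"], "famB", representative="c")]
    )
    p = tmp_path / "groups.tsv"
    write_groups_tsv(cmap, p)
    df = pd.read_csv(p, sep="\t")
    assert list(df.columns) == ["group_id", "sup_category", "representative", "members"]
    assert df.loc[0, "members"] == "a;b"
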