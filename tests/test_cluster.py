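import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import reference_mcl
from conftest import families_of_groups
from pantrait import build_graph, copy_number_matrix, core_groups, mcl
from pantrait.align import HIT_COLUMNS
from pantrait.cluster import partition_to_frame


def hit_row(q, s, evalue, pident=90.0):
    return dict(zip(HIT_COLUMNS + ["raw_score"],
                    [q, s, pident, 100, 5, 0, 1, 100, 1, 100, evalue, 50.0, 100.0]))


def hits_frame(rows):
    base = [hit_row(g, g, 1e-200, 100.0) for g in {r[0] for r in rows} | {r[1] for r in rows}]
    return pd.DataFrame(base + [hit_row(*r) for r in rows])


class TestBuildGraph:
    def test_reciprocal_pair_weight_is_mean_neglog(self):
        g = build_graph(hits_frame([("a", "b", 1e-10), ("b", "a", 1e-20)]))
        assert g["a"]["b"]["weight"] == pytest.approx(15.0)

    def test_one_directional_hit_makes_no_edge(self):
        g = build_graph(hits_frame([("a", "b", 1e-10)]))
        assert not g.has_edge("a", "b")
        assert g.number_of_nodes() == 2  # self-hits still register the genes

    def test_hit_above_cutoff_excluded(self):
        g = build_graph(hits_frame([("a", "b", 1e-3), ("b", "a", 1e-20)]), max_evalue=1e-5)
        assert not g.has_edge("a", "b")

    def test_zero_evalue_capped_at_ceiling(self):
        g = build_graph(hits_frame([("a", "b", 0.0), ("b", "a", 0.0)]))
        assert g["a"]["b"]["weight"] == pytest.approx(300.0)

    def test_identity_cutoff(self):
        g = build_graph(
            hits_frame([("a", "b", 1e-10, 30.0), ("b", "a", 1e-10, 30.0)]), min_identity=0.5
        )
        assert not g.has_edge("a", "b")


def barbell_graph(weight_bridge=0.1, weight_clique=10.0):
    g = nx.Graph()
    for offset in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(offset + i, offset + j, weight=weight_clique)
    g.add_edge(3, 4, weight=weight_bridge)
    return g


class TestMCL:
    def test_disconnected_triangles_stay_separate(self):
        g = nx.Graph()
        for offset in (0, 10):
            g.add_weighted_edges_from(
                [(offset, offset + 1, 1.0), (offset + 1, offset + 2, 1.0), (offset, offset + 2, 1.0)]
            )
        clusters = mcl(g)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2], [10, 11, 12]]

    def test_single_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcl(g) == [{"solo"}]

    def test_barbell_splits_at_bridge(self):
        clusters = mcl(barbell_graph(), inflation=1.5)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_matches_reference_implementation_on_barbell(self):
        g = barbell_graph()
        edges = {(u, v): d["weight"] for u, v, d in g.edges(data=True)}
        ref = reference_mcl(edges, 8, inflation=1.5)
        ours = mcl(g, inflation=1.5)
        assert sorted(map(sorted, ref)) == sorted(map(sorted, ours))

    def test_inflation_must_exceed_one(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        with pytest.raises(ValueError):
            mcl(g, inflation=1.0)


class TestCopyNumberMatrix:
    def setup_method(self):
        self.clusters = [{"s1.g1", "s1.g2", "s2.g1"}, {"s2.g2"}]
        self.gene2strain = {"s1.g1": "s1", "s1.g2": "s1", "s2.g1": "s2", "s2.g2": "s2"}

    def test_copy_counts(self):
        m = copy_number_matrix(self.clusters, ["s1", "s2"], self.gene2strain)
        assert m.iloc[0].tolist() == [2, 1]  # group with two s1 genes
        assert m.loc[:, "s1"].sum() == 2 and m.loc[:, "s2"].sum() == 2

    def test_absent_strain_is_zero(self):
        m = copy_number_matrix(self.clusters, ["s1", "s2", "s3"], self.gene2strain)
        assert (m["s3"] == 0).all()

    def test_column_sums_conserve_proteome_sizes(self, small_matrix, small_cohort):
        matrix, _ = small_matrix
        _, proteomes, *_ = small_cohort
        for p in proteomes:
            assert matrix[p.strain_id].sum() == len(p)

    def test_unmapped_gene_rejected(self):
        with pytest.raises(ValueError, match="no strain mapping"):
            copy_number_matrix([{"mystery"}], ["s1"], {})


class TestCoreGroups:
    def test_core_requires_presence_everywhere(self):
        m = pd.DataFrame({"s1": [1, 1], "s2": [2, 0]}, index=["g1", "g2"])
        assert core_groups(m, ["s1", "s2"]) == {"g1"}

    def test_singleton_strain_set(self):
        m = pd.DataFrame({"s1": [1, 0]}, index=["g1", "g2"])
        assert core_groups(m, ["s1"]) == {"g1"}

    def test_empty_strain_set_rejected(self):
        m = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            core_groups(m, [])


class TestPartitionProperties:
    def test_partition_covers_all_genes_disjointly(self, small_matrix, small_cohort):
        _, partition = small_matrix
        _, proteomes, *_ = small_cohort
        all_genes = {g for p in proteomes for g, _ in p}
        assert set(partition["gene"]) == all_genes
        assert not partition["gene"].duplicated().any()

    def test_clusters_recover_planted_families_exactly(self, small_matrix):
        """Each ortholog group corresponds to exactly one planted family (ARI 1)."""
        _, partition = small_matrix
        fams = families_of_groups(partition)
        assert all(len(f) == 1 for f in fams.values())
        # and no family is split across groups
        seen: dict[str, int] = {}
        for f in fams.values():
            fam = next(iter(f))
            seen[fam] = seen.get(fam, 0) + 1
        assert all(v == 1 for v in seen.values())

    def test_gene_relabeling_permutes_partition(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 5.0), ("c", "d", 5.0)])
        relabeled = nx.relabel_nodes(g, {"a": "z", "b": "y", "c": "x", "d": "w"})
        orig = {frozenset(c) for c in mcl(g)}
        remap = {"z": "a", "y": "b", "x": "c", "w": "d"}
        back = {frozenset(remap[n] for n in c) for c in mcl(relabeled)}
        assert orig == back


def test_partition_frame_ids_are_deterministic():
    part = partition_to_frame([{"b", "a"}, {"c"}])
    assert part.loc[part.gene == "a", "group"].iloc[0] == "OG0001"
    assert part.loc[part.gene == "c", "group"].iloc[0] == "OG0002"
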