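"""Concatenation, distances, neighbor joining and node frequencies."""

import math

import numpy as np
import pytest

from deepsplit import (
    Alignment, DistanceMatrix, InputError, annotate_newick, bipartitions,
    canonical_bipartition, concatenate, neighbor_joining, node_frequencies,
    poisson_distance, read_newick,
)
from deepsplit.trees import (
    build_tree, path_distance_matrix, read_support_newick, support_table,
)

from helpers import (
    leaf_path_distances, random_additive_tree, random_newick, tree_splits,
)


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(InputError, match="unequal"):
            Alignment({"a": "ACD", "b": "AC"})

    def test_concatenate_additivity_and_ranges(self):
        g1 = Alignment({"a": "ACDEF", "b": "ACDEF"})
        g2 = Alignment({"a": "GHIKLMN", "b": "GHIKLMN"})
        concat, ranges = concatenate({"g1": g1, "g2": g2})
        assert concat.length == 12
        assert ranges == {"g1": (1, 5), "g2": (6, 12)}

    def test_single_gene_identity(self):
        g1 = Alignment({"a": "ACDEF", "b": "GHIKL"})
        concat, _ = concatenate({"g1": g1})
        assert concat.rows == g1.rows

    def test_taxon_mismatch_lists_symmetric_difference(self):
        g1 = Alignment({"a": "ACD", "b": "ACD"})
        g2 = Alignment({"a": "ACD", "c": "ACD"})
        with pytest.raises(InputError, match="b, c"):
            concatenate({"g1": g1, "g2": g2})

    def test_gene_order_does_not_change_distances(self, rng):
        rows1 = {f"t{i}": "".join(rng.choice(list("ACDEFG"), size=30))
                 for i in range(5)}
        rows2 = {t: "".join(rng.choice(list("ACDEFG"), size=40))
                 for t in rows1}
        a, b = Alignment(rows1), Alignment(rows2)
        d1 = poisson_distance(concatenate({"g1": a, "g2": b})[0])
        d2 = poisson_distance(concatenate({"g2": b, "g1": a})[0])
        np.testing.assert_allclose(d1.values, d2.values)


class TestPoissonDistance:
    def test_identical_rows(self):
        d = poisson_distance(Alignment({"a": "ACDEF", "b": "ACDEF"}))
        assert d.values[0, 1] == 0.0

    def test_half_different_sites(self):
        d = poisson_distance(Alignment({"a": "AAAAAAAAAA",
                                        "b": "AAAAACCCCC"}))
        assert d.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_pairwise_deletion_matches_column_recount(self, rng):
        rows = {}
        for t in ("a", "b", "c"):
            chars = rng.choice(list("ACDE-"), size=60)
            rows[t] = "".join(chars)
        # ensure comparability
        rows["a"] = "A" * 60
        aln = Alignment(rows)
        d = poisson_distance(aln)
        ids = sorted(rows)
        for i in range(3):
            for j in range(i + 1, 3):
                ri, rj = rows[ids[i]], rows[ids[j]]
                comp = [(x, y) for x, y in zip(ri, rj)
                        if x != "-" and y != "-"]
                p = sum(1 for x, y in comp if x != y) / len(comp)
                want = -math.log(1 - p) if p < 1 - 1e-9 else 10.0
                assert d.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_no_comparable_sites_names_the_pair(self):
        aln = Alignment({"a": "AC--", "b": "--AC", "c": "ACAC"})
        with pytest.raises(InputError, match="'a' and 'b'"):
            poisson_distance(aln)

    def test_saturated_pair_capped(self):
        d = poisson_distance(Alignment({"a": "AAAA", "b": "CCCC"}), d_max=10.0)
        assert d.values[0, 1] == 10.0


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances from ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], D))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        np.testing.assert_allclose(path_distance_matrix(tree).values, D,
                                   atol=1e-9)

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        np.testing.assert_allclose(path_distance_matrix(tree).values, D,
                                   atol=1e-9)

    def test_random_additive_recovery(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            adj = random_additive_tree(rng, n)
            names = [f"t{i:02d}" for i in range(n)]
            D = leaf_path_distances(adj, n)
            tree = neighbor_joining(DistanceMatrix(names, D))
            assert bipartitions(tree) == tree_splits(adj, names)
            np.testing.assert_allclose(path_distance_matrix(tree).values, D,
                                       atol=1e-9)

    def test_ultrametric_blocks_split(self):
        ids = list("abcdef")
        D = np.full((6, 6), 1.0)
        D[:3, :3] = 0.2
        D[3:, 3:] = 0.2
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        assert frozenset("def") in bipartitions(tree)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(["a", "b", "c", "d"],
                                            np.arange(16.0).reshape(4, 4)))
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0]], float)))


class TestBipartitions:
    def test_four_taxa_single_split(self):
        tree = read_newick("((A,B),(C,D));")
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_caterpillar_has_n_minus_3(self):
        tree = read_newick("(A,(B,(C,(D,(E,F)))));")
        assert len(bipartitions(tree)) == 3

    def test_canonicalization_is_side_symmetric(self):
        taxa = {"A", "B", "C", "D"}
        assert canonical_bipartition({"A", "B"}, taxa) == \
               canonical_bipartition({"C", "D"}, taxa)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            bipartitions(read_newick("((A,A),(C,D));"))


class TestNodeFrequencies:
    def test_direct_count(self):
        ref = read_newick("((A,B),(C,D));")
        genes = [read_newick("((A,B),(C,D));"),
                 read_newick("((A,C),(B,D));"),
                 read_newick("((A,B),(C,D));")]
        support = node_frequencies(ref, genes)
        assert support.frequencies[frozenset({"C", "D"})] == pytest.approx(2 / 3)

    def test_identical_gene_trees_give_unit_support(self, rng):
        nwk = random_newick(rng, [f"t{i}" for i in range(8)])
        ref = read_newick(nwk)
        support = node_frequencies(ref, [read_newick(nwk) for _ in range(5)])
        assert set(support.frequencies.values()) == {1.0}
        assert len(support.counts) == 8 - 3

    def test_leaf_set_mismatch(self):
        ref = read_newick("((A,B),(C,D));")
        with pytest.raises(InputError, match="E"):
            node_frequencies(ref, [read_newick("((A,B),(C,E));")])


class TestAnnotatedNewick:
    def test_format_and_round_trip(self):
        ref = read_newick("((A,B),(C,D));")
        genes = [read_newick("((A,B),(C,D));"),
                 read_newick("((A,C),(B,D));"),
                 read_newick("((A,B),(C,D));")]
        support = node_frequencies(ref, genes)
        nwk = annotate_newick(ref, support)
        assert "0.6667" in nwk
        _tree, supports = read_support_newick(nwk)
        assert supports[frozenset({"C", "D"})] == pytest.approx(0.6667)

    def test_round_trip_preserves_everything(self, rng):
        nwk = random_newick(rng, [f"t{i}" for i in range(7)])
        ref = read_newick(nwk)
        genes = [read_newick(random_newick(rng, [f"t{i}" for i in range(7)]))
                 for _ in range(6)]
        support = node_frequencies(ref, genes)
        tree2, supports = read_support_newick(annotate_newick(ref, support))
        assert bipartitions(tree2) == bipartitions(ref)
        for bip, freq in support.frequencies.items():
            assert supports[bip] == pytest.approx(freq, abs=1e-4)

    def test_missing_support_entry(self):
        ref = read_newick("((A,B),(C,D));")
        other = read_newick("((A,C),(B,D));")
        support = node_frequencies(other, [other])
        with pytest.raises(InputError, match="no support entry"):
            annotate_newick(ref, support)

    def test_support_table_is_tidy(self):
        ref = read_newick("((A,B),(C,D));")
        support = node_frequencies(ref, [ref])
        df = support_table(support)
        assert list(df.columns) == ["bipartition", "count", "frequency"]
        assert df.iloc[0]["frequency"] == 1.0


def test_no_discordance_gives_unit_support_end_to_end(tiny_taxonomy):
    """With p = 0, every node of the species tree reaches frequency 1.0."""
    from deepsplit import SimulationConfig, simulate_gene_trees_and_alignments

    cfg, group_map, species_tree = tiny_taxonomy
    cfg = SimulationConfig(**{**cfg.__dict__, "discordance_prob": 0.0})
    _trees, alignments, _pert = simulate_gene_trees_and_alignments(
        cfg, species_tree, group_map)
    concat, _ = concatenate(alignments)
    ref = build_tree(concat)
    assert bipartitions(ref) == bipartitions(species_tree)
    support = node_frequencies(
        ref, [build_tree(a) for a in alignments.values()])
    assert set(support.frequencies.values()) == {1.0}


def test_build_tree_recovers_generating_topology(rng):
    """NJ on Poisson distances from simulated sequences finds the true tree."""
    from deepsplit.simulate import evolve_sequences

    nwk = random_newick(rng, [f"t{i}" for i in range(6)])
    tree = read_newick(nwk)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = 0.2
    rows = evolve_sequences(tree, 3000, rng)
    inferred = build_tree(Alignment(rows))
    assert bipartitions(inferred) == bipartitions(tree)
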