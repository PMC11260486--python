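"""MinHash sketches, Mash distances, similarity networks and Louvain species."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import linchrom as lc
from linchrom.io import LinearChromosome, reverse_complement


def random_genome(L, seed):
    return lc.generate_species_set(1, 1, 0.0, L=L, seed=seed)[0][0]


def brute_force_mash(seq_a, seq_b, k=21):
    """Exact full-k-mer-set Jaccard plugged into the Mash distance formula."""
    def canon(s):
        return {min(s[i : i + k], reverse_complement(s[i : i + k])) for i in range(len(s) - k + 1)}

    a, b = canon(seq_a), canon(seq_b)
    j = len(a & b) / len(a | b)
    if j == 0:
        return 1.0
    return -math.log(2 * j / (1 + j)) / k


class TestSketch:
    def test_deterministic(self):
        g = random_genome(5_000, seed=1)
        a, b = lc.minhash_sketch(g), lc.minhash_sketch(g)
        assert np.array_equal(a.hashes, b.hashes)

    def test_reverse_complement_invariant(self):
        g = random_genome(5_000, seed=2)
        rc = LinearChromosome("rc", reverse_complement(g.seq))
        assert np.array_equal(lc.minhash_sketch(g).hashes, lc.minhash_sketch(rc).hashes)

    def test_small_genome_keeps_all_kmers(self):
        g = random_genome(200, seed=3)
        sketch = lc.minhash_sketch(g, s=1000)
        k = 21
        distinct = {min(g.seq[i : i + k], reverse_complement(g.seq[i : i + k])) for i in range(len(g.seq) - k + 1)}
        assert sketch.hashes.size == len(distinct) < 1000

    def test_kmers_with_n_skipped(self):
        g = random_genome(100, seed=4)
        with_n = LinearChromosome("n", g.seq[:50] + "N" + g.seq[51:])
        assert lc.minhash_sketch(with_n).hashes.size < lc.minhash_sketch(g).hashes.size

    def test_even_k_is_error(self):
        with pytest.raises(ValueError, match="odd"):
            lc.minhash_sketch(random_genome(100, 0), k=20)

    def test_sequence_shorter_than_k_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            lc.minhash_sketch(LinearChromosome("x", "ACGT"), k=21)


class TestMashDistance:
    def test_identical_genomes_have_zero_distance(self):
        g = random_genome(10_000, seed=5)
        assert lc.mash_distance(lc.minhash_sketch(g), lc.minhash_sketch(g)) == 0.0

    def test_unrelated_genomes_hit_the_cap(self):
        a = lc.minhash_sketch(random_genome(5_000, seed=6))
        b = lc.minhash_sketch(random_genome(5_000, seed=7))
        assert lc.mash_distance(a, b) == 1.0

    def test_close_to_brute_force_jaccard(self):
        genomes, _ = lc.generate_species_set(1, 2, 0.01, L=50_000, seed=8)
        est = lc.mash_distance(*[lc.minhash_sketch(g) for g in genomes])
        true = brute_force_mash(genomes[0].seq, genomes[1].seq)
        assert abs(est - true) < 0.01

    def test_mismatched_k_is_error(self):
        g = random_genome(1_000, seed=9)
        with pytest.raises(ValueError, match="mismatched"):
            lc.mash_distance(lc.minhash_sketch(g, k=21), lc.minhash_sketch(g, k=17))

    def test_symmetric_pseudo_metric(self):
        genomes, _ = lc.generate_species_set(1, 3, 0.02, L=10_000, seed=10)
        sketches = [lc.minhash_sketch(g) for g in genomes]
        table = lc.pairwise_mash_distances(sketches)
        assert np.allclose(table.values, table.values.T)
        assert np.all(np.diag(table.values) == 0)


class TestNetwork:
    def test_single_edge_below_cutoff(self):
        table = pd.DataFrame(
            [[0.0, 0.01, 0.2], [0.01, 0.0, 0.2], [0.2, 0.2, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        graph = lc.build_similarity_network(table, cutoff=0.05)
        assert graph.number_of_edges() == 1 and graph.has_edge("a", "b")

    def test_all_distant_gives_isolates(self):
        table = pd.DataFrame(0.3 * (1 - np.eye(4)), index=list("abcd"), columns=list("abcd"))
        graph = lc.build_similarity_network(table)
        assert graph.number_of_edges() == 0 and graph.number_of_nodes() == 4

    def test_asymmetric_table_is_error(self):
        table = pd.DataFrame([[0.0, 0.1], [0.2, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            lc.build_similarity_network(table)


def all_partitions(items):
    """Every partition of a small set (restricted growth strings)."""
    items = list(items)
    n = len(items)
    def rec(i, groups):
        if i == n:
            yield [set(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()
    yield from rec(0, [])


def modularity_from_scratch(graph, partition):
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j), by the formula."""
    m = graph.number_of_edges()
    community = {node: ci for ci, part in enumerate(partition) for node in part}
    degree = dict(graph.degree)
    q = 0.0
    for i in graph.nodes:
        for j in graph.nodes:
            if community[i] != community[j]:
                continue
            a_ij = 1.0 if graph.has_edge(i, j) else 0.0
            q += a_ij - degree[i] * degree[j] / (2 * m)
    return q / (2 * m)


class TestLouvain:
    def test_single_node(self):
        graph = nx.Graph()
        graph.add_node("only")
        communities, q = lc.louvain_communities(graph, seed=1)
        assert communities == {"only": 0} and q == 0.0

    def test_two_disjoint_triangles_reach_the_exhaustive_optimum(self):
        graph = nx.Graph()
        graph.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        communities, q = lc.louvain_communities(graph, seed=3)
        best = max(modularity_from_scratch(graph, p) for p in all_partitions(range(6)))
        assert best == pytest.approx(0.5)
        assert q == pytest.approx(best)
        assert len(set(communities.values())) == 2
        assert len({communities[0], communities[1], communities[2]}) == 1

    def test_partition_beats_trivial_partitions(self, species_set):
        genomes, _ = species_set
        sketches = [lc.minhash_sketch(g) for g in genomes]
        graph = lc.build_similarity_network(lc.pairwise_mash_distances(sketches))
        communities, q = lc.louvain_communities(graph, seed=0)
        singletons = [{n} for n in graph.nodes]
        assert q >= nx.community.modularity(graph, singletons)
        assert q >= nx.community.modularity(graph, [set(graph.nodes)])

    def test_planted_clusters_recovered(self, species_set):
        genomes, truth = species_set
        sketches = [lc.minhash_sketch(g) for g in genomes]
        graph = lc.build_similarity_network(lc.pairwise_mash_distances(sketches), cutoff=0.05)
        communities, _ = lc.louvain_communities(graph, seed=5)
        labels = dict(zip(truth.genome_id, truth.cluster))
        for a, b in itertools.combinations(graph.nodes, 2):
            assert (communities[a] == communities[b]) == (labels[a] == labels[b])

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            lc.louvain_communities(nx.Graph())


class TestSpeciesSummary:
    def test_pair_plus_isolates(self):
        summary = lc.species_summary({"a": 0, "b": 0, "c": 1, "d": 2, "e": 3})
        assert summary["n_species"] == 4 and summary["n_singletons"] == 3
        assert summary["sizes"] == [2, 1, 1, 1]

    def test_one_big_community(self):
        summary = lc.species_summary({f"g{i}": 0 for i in range(10)})
        assert summary["n_species"] == 1 and summary["n_singletons"] == 0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            lc.species_summary({})
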