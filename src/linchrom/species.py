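"""MinHash genome sketching, Mash distances and species delineation.

Genomes are reduced to bottom-s MinHash sketches of their canonical k-mers;
pairwise Mash distances D = -ln(2j/(1+j))/k estimate genome dissimilarity
from the Jaccard estimate j.  Genomes closer than a distance cutoff (default
0.05, i.e. 95% similarity) are joined in an unweighted similarity network,
and Louvain communities of that network are reported as computational
species.

The k-mer hash is a splitmix64 finalizer applied to the 2-bit encoding of the
canonical k-mer (the lexicographic minimum of the k-mer and its reverse
complement), vectorized over the genome.  With k = 21 a k-mer fits in 42 bits,
so the encoding is collision-free before hashing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import LinearChromosome

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = x + _GOLDEN
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@dataclass
class GenomeSketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted ascending, distinct, dtype uint64
    hash_seed: int = 42

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if np.any(np.diff(self.hashes.view(np.uint64)) <= 0) and self.hashes.size > 1:
            raise ValueError("sketch hashes must be sorted ascending and distinct")


def canonical_kmer_hashes(seq: str, k: int, hash_seed: int = 42) -> np.ndarray:
    """Distinct splitmix64 hash values of all canonical k-mers of ``seq``.

    K-mers containing N (or any non-ACGT base) are skipped.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    n_win = codes.size - k + 1
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rc = np.zeros(n_win, dtype=np.uint64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        window = c64[j : j + n_win]
        fwd = fwd * _U64(4) + window
        rc = rc + (_U64(3) - window) * (_U64(4) ** _U64(j))
        valid &= codes[j : j + n_win] < 4
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    canon = np.minimum(fwd[valid], rc[valid])
    seeded = canon ^ _splitmix64(np.array([hash_seed], dtype=np.uint64))[0]
    return np.unique(_splitmix64(seeded))


def minhash_sketch(
    chromosomes: LinearChromosome | list[LinearChromosome],
    genome_id: str | None = None,
    k: int = 21,
    s: int = 1000,
    hash_seed: int = 42,
) -> GenomeSketch:
    """Bottom-s MinHash sketch of one genome (one or several replicons).

    ``k`` must be odd so no k-mer equals its own reverse complement.  If the
    genome has fewer than ``s`` distinct k-mers the sketch simply holds all
    of them.
    """
    if isinstance(chromosomes, LinearChromosome):
        chromosomes = [chromosomes]
    if not chromosomes:
        raise ValueError("minhash_sketch needs at least one replicon")
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if max(c.length for c in chromosomes) < k:
        raise ValueError("all sequences shorter than k")
    hashes = np.unique(np.concatenate([canonical_kmer_hashes(c.seq, k, hash_seed) for c in chromosomes]))
    if hashes.size == 0:
        raise ValueError("no valid k-mers (all windows contain N)")
    return GenomeSketch(
        genome_id=genome_id or chromosomes[0].id, k=k, s=s,
        hashes=hashes[:s], hash_seed=hash_seed,
    )


def mash_distance(a: GenomeSketch, b: GenomeSketch) -> float:
    """Mash distance between two sketches.

    The Jaccard index j is estimated from the s smallest hashes of the merged
    sketch (how many occur in both genomes), then
    D = -(1/k) * ln(2j / (1+j)), capped at 1 for disjoint sketches.
    """
    if a.k != b.k or a.hash_seed != b.hash_seed:
        raise ValueError("sketches have mismatched k or hash seed")
    merged = np.union1d(a.hashes, b.hashes)
    bottom = merged[: min(a.s, b.s)]
    shared = int((np.isin(bottom, a.hashes) & np.isin(bottom, b.hashes)).sum())
    j = shared / bottom.size
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    d = -np.log(2 * j / (1 + j)) / a.k
    return float(min(d, 1.0))


def pairwise_mash_distances(sketches: list[GenomeSketch]) -> pd.DataFrame:
    """Symmetric distance matrix over a list of sketches."""
    ids = [s.genome_id for s in sketches]
    n = len(sketches)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = mash_distance(sketches[i], sketches[j])
    return pd.DataFrame(dist, index=ids, columns=ids)


def build_similarity_network(distances: pd.DataFrame, cutoff: float = 0.05) -> nx.Graph:
    """Unweighted genome similarity network: edge iff distance <= cutoff.

    Nodes without any edge are retained as isolates.  The distance table must
    be symmetric to 1e-12.
    """
    values = distances.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-12, rtol=0):
        raise ValueError("distance table is not symmetric")
    graph = nx.Graph()
    ids = list(distances.index)
    graph.add_nodes_from(ids)
    for i, u in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if values[i, j] <= cutoff:
                graph.add_edge(u, ids[j])
    return graph


def louvain_communities(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[dict[str, int], float]:
    """Louvain community detection; returns node->community map and modularity Q.

    Standard two-phase Louvain (local modularity-gain moves, then graph
    aggregation, repeated to convergence) with the node visit order shuffled
    by ``seed``.  Isolates end up in singleton communities; an edgeless graph
    has Q = 0 by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(graph.nodes)}, 0.0
    parts = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
    membership = {node: i for i, part in enumerate(parts) for node in part}
    q = nx.community.modularity(graph, parts, resolution=resolution)
    return membership, float(q)


def species_summary(communities: dict[str, int]) -> dict:
    """Community count, singleton count and the community size distribution."""
    if not communities:
        raise ValueError("no communities assigned")
    sizes = pd.Series(list(communities.values())).value_counts().sort_values(ascending=False)
    return {
        "n_species": int(sizes.size),
        "n_singletons": int((sizes == 1).sum()),
        "sizes": sizes.tolist(),
    }
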