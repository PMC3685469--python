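"""Balanced taxon sampling by clustering marker-protein identities.

The procedure mirrors broad-sampling selection from a large genome
collection: all-vs-all identities of a single marker protein (ribosomal
protein L3 in the motivating analysis) are converted to distances, each
domain is clustered hierarchically (average linkage by default), the
dendrogram is cut into ``k`` clusters per domain, and each cluster
contributes its medoid, giving a deterministic 50/50-style sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import ConfigError, InputError
from .families import pairwise_identity
from .io import GroupMap

LINKAGES = ("average", "single", "complete")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over an ordered taxon list (zero diagonal)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise InputError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-9):
            raise InputError("distance matrix is not symmetric")
        if np.diag(v).any():
            raise InputError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise InputError("distance matrix has negative entries")
        self.values = v

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


def marker_distance_matrix(marker_seqs: Mapping[str, str],
                           genomes: list[str] | None = None) -> DistanceMatrix:
    """All-vs-all marker identities converted to distances (1 - identity/100).

    ``marker_seqs`` maps genome id -> marker protein sequence; if ``genomes``
    is given, every listed genome must have a marker.
    """
    if genomes is not None:
        missing = sorted(set(genomes) - set(marker_seqs))
        if missing:
            raise InputError(
                f"no marker sequence for genome(s): {', '.join(missing)}"
            )
        ids = sorted(genomes)
    else:
        ids = sorted(marker_seqs)
    if len(ids) < 2:
        raise InputError("need >=2 genomes for a distance matrix")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(marker_seqs[ids[i]], marker_seqs[ids[j]])
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(ids, d)


def _medoid(ids: list[str], d: np.ndarray, members: np.ndarray) -> str:
    sums = d[np.ix_(members, members)].sum(axis=1)
    best = sums.min()
    # ties broken by lexicographically smallest genome id
    candidates = [ids[members[i]] for i in range(len(members))
                  if sums[i] <= best + 1e-12]
    return min(candidates)


def cluster_domain(dm: DistanceMatrix, k: int,
                   linkage_method: str = "average") -> list[str]:
    """Cut an average-linkage dendrogram into ``k`` clusters; return medoids."""
    if linkage_method not in LINKAGES:
        raise ConfigError(f"linkage must be one of {LINKAGES}")
    n = len(dm.ids)
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} outside [1, {n}] for this domain")
    # canonical (sorted-id) order makes the result independent of input order
    order = sorted(range(n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    d = dm.values[np.ix_(order, order)]
    if k == n:
        return ids
    z = linkage(squareform(d, checks=False), method=linkage_method)
    labels = fcluster(z, t=k, criterion="maxclust")
    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        reps.append(_medoid(ids, d, members))
    return sorted(reps)


def cluster_and_sample(dm: DistanceMatrix, group_map: GroupMap,
                       k_per_domain: int,
                       linkage_method: str = "average") -> list[str]:
    """Select ``k_per_domain`` medoid representatives from each domain.

    The two domains are clustered independently so the sample is exactly
    balanced; returns the sorted union (size ``2 * k_per_domain``).
    """
    group_map.require(dm.ids, context="distance matrix")
    selected: list[str] = []
    for domain in ("archaebacteria", "eubacteria"):
        members = [g for g in dm.ids if group_map.domain_of(g) == domain]
        if len(members) < k_per_domain:
            raise ConfigError(
                f"k_per_domain={k_per_domain} exceeds the {len(members)} "
                f"{domain} genomes"
            )
        selected.extend(cluster_domain(dm.submatrix(members), k_per_domain,
                                       linkage_method))
    return sorted(selected)


def dendrogram_newick(dm: DistanceMatrix,
                      linkage_method: str = "average") -> str:
    """Export the domain dendrogram as Newick for inspection.

    Branch lengths are half the difference of merge heights (ultrametric
    convention).
    """
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    d = dm.values[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method=linkage_method)
    root = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});\n"
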