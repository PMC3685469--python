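"""Gene-tree vs concatenated-tree support: the disappearing-tree statistic.

Per-gene protein alignments over one shared taxon set are concatenated into a
supermatrix; trees are built by neighbor joining on Poisson-corrected
p-distances (deterministic and fast; externally built Newick trees are
accepted anywhere a tree is expected, so the support statistic itself is
method-agnostic).  Every internal edge of the reference (concatenated) tree
defines a bipartition of the taxon set; its *node frequency* is the fraction
of single-gene trees whose own bipartition set contains it exactly.  The
annotated Newick export carries those frequencies as internal-node labels so
a viewer can render branch transparency from them.

All trees are treated as unrooted; bipartitions are canonicalized as the
leaf subset NOT containing the lexicographically smallest taxon id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import InputError
from .io import iter_fasta, tree_to_newick, write_fasta

Bipartition = frozenset  # canonical leaf subset, see canonical_bipartition()

GAP = "-"


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length aligned amino-acid rows keyed by taxon id (1-based columns)."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise InputError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        rows: dict[str, str] = {}
        for name, seq in iter_fasta(path):
            if name in rows:
                raise InputError(f"{path}: duplicate taxon id {name!r}")
            rows[name] = seq
        return cls(rows)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.rows.items())


def concatenate(alignments: Mapping[str, Alignment],
                ) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Row-wise concatenation of per-gene alignments over one shared taxon set.

    Returns the supermatrix and the 1-based inclusive column range of each
    gene.  A taxon-set mismatch between genes is an error (no gap padding).
    """
    if not alignments:
        raise InputError("no alignments to concatenate")
    gene_ids = list(alignments)
    ref_taxa = set(alignments[gene_ids[0]].rows)
    for gene in gene_ids[1:]:
        taxa = set(alignments[gene].rows)
        if taxa != ref_taxa:
            diff = sorted(taxa ^ ref_taxa)
            raise InputError(
                f"gene {gene!r}: taxon set differs from {gene_ids[0]!r}; "
                f"symmetric difference: {', '.join(diff)}"
            )
    order = sorted(ref_taxa)
    parts: dict[str, list[str]] = {t: [] for t in order}
    ranges: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene in gene_ids:
        aln = alignments[gene]
        ranges[gene] = (pos + 1, pos + aln.length)
        pos += aln.length
        for t in order:
            parts[t].append(aln.rows[t])
    return Alignment({t: "".join(parts[t]) for t in order}), ranges


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def poisson_distance(alignment: Alignment, d_max: float = 10.0) -> "DistanceMatrix":
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the proportion of differing sites among sites where neither row is
    a gap (pairwise deletion).  p >= 1 - 1e-9 is capped at ``d_max``; a pair
    with no comparable sites is an error.
    """
    from .sampling import DistanceMatrix

    ids = sorted(alignment.rows)
    if len(ids) < 2:
        raise InputError("need >=2 taxa for distances")
    mat = np.array([list(alignment.rows[t].encode()) for t in ids], dtype=np.uint8)
    gap = mat == ord(GAP)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & ok
        comparable = ok.sum(axis=1)
        for off, (nc, nd) in enumerate(zip(comparable, diff.sum(axis=1))):
            j = i + 1 + off
            if nc == 0:
                raise InputError(
                    f"taxa {ids[i]!r} and {ids[j]!r} share no ungapped sites"
                )
            p = nd / nc
            dist = d_max if p >= 1 - 1e-9 else -math.log(1.0 - p)
            d[i, j] = d[j, i] = min(dist, d_max)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm) -> dendropy.Tree:
    """Neighbor joining on the Q-criterion; deterministic and unrooted.

    Ties in Q are broken by the smallest (row, column) index pair; negative
    limb estimates are clamped to 0.  With three taxa the unique star
    resolution is returned.  Exact on additive matrices.
    """
    ids = list(dm.ids)
    d = np.array(dm.values, dtype=float)
    n = len(ids)
    if n < 3:
        raise InputError("neighbor joining needs >=3 taxa")

    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = ns.require_taxon(label)
        nodes.append(node)

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        q = (r - 2) * d - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(r, k=1)
        qvals = q[iu]
        best = qvals.min()
        flat = np.flatnonzero(qvals == best)[0]  # row-major => smallest (i, j)
        i, j = iu[0][flat], iu[1][flat]
        dij = d[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        du = np.maximum(0.5 * (d[i] + d[j] - dij), 0.0)
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)],
                       du[keep][None, :]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    root = dendropy.Node()
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.edge.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.edge.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.edge.length = max(0.5 * (dac + dbc - dab), 0.0)
    for child in (a, b, c):
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def build_tree(alignment: Alignment, d_max: float = 10.0) -> dendropy.Tree:
    """Convenience: Poisson distances then neighbor joining."""
    return neighbor_joining(poisson_distance(alignment, d_max=d_max))


# ---------------------------------------------------------------------------
# Bipartitions and node frequencies
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise InputError(f"duplicate leaf labels: {', '.join(dup)}")
    return labels


def canonical_bipartition(side: Iterable[str], all_taxa: Iterable[str]) -> Bipartition:
    """Canonical form of a split: the side NOT containing the smallest taxon."""
    side = frozenset(side)
    all_taxa = frozenset(all_taxa)
    if not side or side == all_taxa:
        raise InputError("bipartition side must be a proper non-empty subset")
    if min(all_taxa) in side:
        side = all_taxa - side
    return side


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Canonical non-trivial bipartitions, one per internal edge.

    Trivial (single-leaf) splits are excluded; for a binary unrooted tree on
    n leaves the result has n - 3 elements.
    """
    taxa = frozenset(leaf_labels(tree))
    if len(taxa) < 4:
        return set()
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        out.add(canonical_bipartition(side, taxa))
    return out


@dataclass
class SupportAnnotation:
    """Bipartition -> count among gene trees, for a fixed reference tree."""

    counts: dict[Bipartition, int]
    n_gene_trees: int

    @property
    def frequencies(self) -> dict[Bipartition, float]:
        return {b: c / self.n_gene_trees for b, c in self.counts.items()}


def node_frequencies(ref_tree: dendropy.Tree,
                     gene_trees: Sequence[dendropy.Tree]) -> SupportAnnotation:
    """Frequency of each reference-tree bipartition among the gene trees.

    Matching is exact bipartition identity; every gene tree must share the
    reference tree's leaf set.
    """
    if not gene_trees:
        raise InputError("no gene trees supplied")
    ref_taxa = frozenset(leaf_labels(ref_tree))
    gene_bips = []
    for idx, gt in enumerate(gene_trees):
        taxa = frozenset(leaf_labels(gt))
        if taxa != ref_taxa:
            diff = sorted(taxa ^ ref_taxa)
            raise InputError(
                f"gene tree {idx}: leaf set differs from reference; "
                f"symmetric difference: {', '.join(diff)}"
            )
        gene_bips.append(bipartitions(gt))
    counts = {
        b: sum(1 for gb in gene_bips if b in gb)
        for b in bipartitions(ref_tree)
    }
    return SupportAnnotation(counts, len(gene_trees))


def support_table(support: SupportAnnotation):
    """Tidy per-bipartition table (members, count, frequency)."""
    import pandas as pd

    rows = [
        {
            "bipartition": ",".join(sorted(b)),
            "count": c,
            "frequency": c / support.n_gene_trees,
        }
        for b, c in sorted(support.counts.items(),
                           key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["bipartition", "count", "frequency"])


def annotate_newick(tree: dendropy.Tree, support: SupportAnnotation) -> str:
    """Newick with node frequencies (4 decimals) as internal-node labels.

    Round-trips through :func:`read_support_newick`.  Raises if any internal
    edge of the tree lacks a support entry.
    """
    taxa = frozenset(leaf_labels(tree))
    freqs = support.frequencies
    annotated = dendropy.Tree(tree)  # deep copy, same namespace
    for node in annotated.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        bip = canonical_bipartition(side, taxa)
        if bip not in freqs:
            raise InputError(
                f"no support entry for bipartition {sorted(bip)}"
            )
        node.label = f"{freqs[bip]:.4f}"
    return tree_to_newick(annotated)


def read_support_newick(source: str | Path,
                        ) -> tuple[dendropy.Tree, dict[Bipartition, float]]:
    """Parse an annotated Newick back into (tree, bipartition -> frequency)."""
    from .io import read_newick

    tree = read_newick(source)
    taxa = frozenset(leaf_labels(tree))
    supports: dict[Bipartition, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf() or node.label is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        supports[canonical_bipartition(side, taxa)] = float(node.label)
    return tree, supports


def path_distance_matrix(tree: dendropy.Tree):
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    from .sampling import DistanceMatrix

    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids, d)
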