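"""Synthetic data generator with full ground truth for every pipeline stage.

The generator emulates the shape of the real inputs — two prokaryotic
domains split into higher taxonomic groups, per-genome proteomes, ortholog
families with controlled group presence and pairwise identity, similarity
hit tables with controlled pass/fail structure, and per-gene trees that
match a known species tree except for seeded discordance events — so that
every downstream operation can be tested against known truth.

Randomness: one integer seed; each stage draws from its own child stream of
a :class:`numpy.random.SeedSequence` (stage order: taxonomy, gene trees and
alignments, proteomes, families, hit table), so outputs are reproducible
regardless of which stages are run and two runs from one seed are
byte-identical.

Discordance model: with probability ``discordance_prob`` a gene receives
exactly one nearest-neighbour interchange at a uniformly chosen internal
edge, the inter-domain edge excluded by default.  This makes each eligible
node's expected gene-tree frequency analytic: 1 - p / n_eligible_edges.

Substitution model: site-independent Poisson-style process; root residues
uniform over the 20 amino acids with the cysteine frequency set by
``background_c_freq``; per branch of length t each site substitutes with
probability 1 - exp(-t), uniformly over the other 19 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError
from .io import (
    ARCHAEBACTERIA, EUBACTERIA, GroupMap, write_fasta, write_hit_table,
    write_newick, write_family_table,
)
from .motifs import AMINO_ACIDS, GENERAL_PATTERN, MotifPattern, DEFAULT_MARKER_SETS
from .pathways import CD1_GENE, DEFAULT_PATHWAYS, PathwayDef
from .trees import Alignment, canonical_bipartition, leaf_labels

_STAGES = {"taxonomy": 0, "genes": 1, "proteomes": 2, "families": 3, "hits": 4}

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_C_INDEX = AMINO_ACIDS.index("C")
_NON_C = np.array([i for i in range(20) if i != _C_INDEX])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator stage."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale constants
    where the analysis states them (11 archaebacterial and 30 eubacterial
    groups, 48 universal genes) and desk-scale choices elsewhere."""

    seed: int = 0
    n_arch_groups: int = 11
    n_eub_groups: int = 30
    genomes_per_group: int = 2
    n_families: int = 100
    family_presence_probs: np.ndarray | None = None
    diverged_family_fraction: float = 0.2
    family_seq_length: int = 200
    member_divergence: float = 0.05
    diverged_divergence: float = 0.9
    n_universal_genes: int = 48
    sites_per_gene: int = 2000
    interdomain_branch: float = 1.0
    branch_length_range: tuple[float, float] = (0.05, 0.15)
    discordance_prob: float = 0.25
    exclude_interdomain: bool = True
    motif_rate: float = 0.05
    background_c_freq: float = 0.014
    proteins_per_genome: int = 50
    protein_length: int = 300
    pathway_truth: dict[str, dict[str, float]] | None = None
    cd1_prob: float = 0.3
    marker_prob: float = 0.3
    decoys_per_genome: int = 2

    def validate(self) -> None:
        counts = {
            "n_arch_groups": self.n_arch_groups,
            "n_eub_groups": self.n_eub_groups,
            "genomes_per_group": self.genomes_per_group,
            "n_families": self.n_families,
            "family_seq_length": self.family_seq_length,
            "n_universal_genes": self.n_universal_genes,
            "sites_per_gene": self.sites_per_gene,
            "proteins_per_genome": self.proteins_per_genome,
            "protein_length": self.protein_length,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name}: must be >= 1, got {value}")
        probs = {
            "diverged_family_fraction": self.diverged_family_fraction,
            "member_divergence": self.member_divergence,
            "diverged_divergence": self.diverged_divergence,
            "discordance_prob": self.discordance_prob,
            "motif_rate": self.motif_rate,
            "background_c_freq": self.background_c_freq,
            "cd1_prob": self.cd1_prob,
            "marker_prob": self.marker_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {value}")
        if self.interdomain_branch <= 0:
            raise ConfigError(
                f"interdomain_branch: must be > 0, got {self.interdomain_branch}"
            )
        lo, hi = self.branch_length_range
        if lo < 0 or hi < lo:
            raise ConfigError(
                f"branch_length_range: need 0 <= lo <= hi, got {self.branch_length_range}"
            )
        if self.decoys_per_genome < 0:
            raise ConfigError("decoys_per_genome: must be >= 0")
        if self.family_presence_probs is not None:
            fpp = np.asarray(self.family_presence_probs, dtype=float)
            n_groups = self.n_arch_groups + self.n_eub_groups
            if fpp.shape != (self.n_families, n_groups):
                raise ConfigError(
                    f"family_presence_probs: shape {fpp.shape} != "
                    f"({self.n_families}, {n_groups})"
                )
            if ((fpp < 0) | (fpp > 1)).any():
                raise ConfigError("family_presence_probs: values outside [0, 1]")

    def to_yaml(self) -> str:
        d = asdict(self)
        if d["family_presence_probs"] is not None:
            d["family_presence_probs"] = np.asarray(
                d["family_presence_probs"]).tolist()
        if d["branch_length_range"] is not None:
            d["branch_length_range"] = list(d["branch_length_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "branch_length_range" in raw:
            raw["branch_length_range"] = tuple(raw["branch_length_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    species_tree_newick: str = ""
    #: gene id -> canonical bipartition destroyed by its NNI, or None
    gene_perturbations: dict[str, frozenset | None] = field(default_factory=dict)
    #: (genome_id, protein_id, 1-based start) of each planted motif
    motif_plantings: list[tuple[str, str, int]] = field(default_factory=list)
    #: family id -> set of groups the family is present in
    family_presence: dict[str, set[str]] = field(default_factory=dict)
    #: families intended to survive the all-pairs identity filter
    family_retained: set[str] = field(default_factory=set)
    #: (genome_id, pathway) -> intended completeness fraction
    pathway_completeness: dict[tuple[str, str], float] = field(default_factory=dict)
    cd1_genomes: set[str] = field(default_factory=set)
    #: taxa carrying at least one marker-complex subunit
    marker_taxa: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Taxonomy and species tree
# ---------------------------------------------------------------------------

def _join_random(nodes: list[dendropy.Node], rng: np.random.Generator,
                 lo: float, hi: float) -> dendropy.Node:
    """Random sequential binary joins; children get uniform(lo, hi) lengths."""
    nodes = list(nodes)
    while len(nodes) > 1:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        nodes.append(parent)
    return nodes[0]


def simulate_taxonomy(config: SimulationConfig,
                      ) -> tuple[GroupMap, dendropy.Tree]:
    """Genome -> (domain, group) map and a binary unrooted species tree.

    Groups cluster together in the tree; the two domains are connected by a
    single inter-domain edge of length ``interdomain_branch``.
    """
    config.validate()
    total = (config.n_arch_groups + config.n_eub_groups) * config.genomes_per_group
    if total < 4:
        raise ConfigError(
            "genomes_per_group: total genome count "
            f"{total} < 4, no binary unrooted species tree exists"
        )
    rng = stage_rng(config.seed, "taxonomy")
    lo, hi = config.branch_length_range

    mapping: dict[str, tuple[str, str]] = {}
    ns = dendropy.TaxonNamespace()
    domain_roots: dict[str, dendropy.Node] = {}
    for domain, prefix, n_groups in (
        (ARCHAEBACTERIA, "arch", config.n_arch_groups),
        (EUBACTERIA, "eub", config.n_eub_groups),
    ):
        group_roots = []
        for g in range(1, n_groups + 1):
            group = f"{prefix}{g:02d}"
            leaves = []
            for m in range(1, config.genomes_per_group + 1):
                genome = f"{group}_g{m:02d}"
                mapping[genome] = (domain, group)
                leaf = dendropy.Node()
                leaf.taxon = ns.require_taxon(genome)
                leaves.append(leaf)
            group_roots.append(_join_random(leaves, rng, lo, hi))
        domain_roots[domain] = _join_random(group_roots, rng, lo, hi)

    arch_root = domain_roots[ARCHAEBACTERIA]
    eub_root = domain_roots[EUBACTERIA]
    # root at the eubacterial side: the arch subtree hangs off the single
    # inter-domain edge, giving a trifurcating (unrooted) representation
    root, other = (eub_root, arch_root) if not eub_root.is_leaf() else (arch_root, eub_root)
    root.add_child(other)
    other.edge.length = float(config.interdomain_branch)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return GroupMap(mapping), tree


def interdomain_bipartition(group_map: GroupMap) -> frozenset:
    """The canonical bipartition separating the two domains."""
    return canonical_bipartition(group_map.genomes(ARCHAEBACTERIA),
                                 group_map.genomes())


# ---------------------------------------------------------------------------
# Gene trees and alignments
# ---------------------------------------------------------------------------

def _internal_nonroot_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    return [
        n for n in tree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
    ]


def _node_bipartition(node: dendropy.Node, taxa: frozenset) -> frozenset:
    side = frozenset(l.taxon.label for l in node.leaf_iter())
    return canonical_bipartition(side, taxa)


def apply_nni(tree: dendropy.Tree, node: dendropy.Node,
              rng: np.random.Generator) -> frozenset:
    """One nearest-neighbour interchange across ``node``'s parent edge.

    Swaps a uniformly chosen child of ``node`` with a uniformly chosen
    sibling subtree; returns the canonical bipartition the edge carried
    before the swap (the destroyed split).
    """
    taxa = frozenset(leaf_labels(tree))
    destroyed = _node_bipartition(node, taxa)
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    children = node.child_nodes()
    sib = siblings[int(rng.integers(len(siblings)))]
    child = children[int(rng.integers(len(children)))]
    parent.remove_child(sib)
    node.remove_child(child)
    parent.add_child(child)
    node.add_child(sib)
    return destroyed


def evolve_sequences(tree: dendropy.Tree, n_sites: int,
                     rng: np.random.Generator,
                     background_c_freq: float = 0.014) -> dict[str, str]:
    """Evolve one alignment along a tree under the Poisson-style model.

    Root residues are uniform over the 20 amino acids with P(C) =
    ``background_c_freq``; on each branch of length t a site substitutes
    with probability 1 - exp(-t), to a residue uniform over the other 19.
    """
    probs = np.full(20, (1.0 - background_c_freq) / 19.0)
    probs[_C_INDEX] = background_c_freq
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.choice(20, size=n_sites, p=probs)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        seq = parent_seq.copy()
        mask = rng.random(n_sites) < (1.0 - np.exp(-t))
        n_sub = int(mask.sum())
        if n_sub:
            # uniform over the 19 non-identical residues
            shift = rng.integers(1, 20, size=n_sub)
            seq[mask] = (seq[mask] + shift) % 20
        seqs[id(node)] = seq
    return {
        leaf.taxon.label: _AA[seqs[id(leaf)]].tobytes().decode()
        for leaf in tree.leaf_node_iter()
    }


def simulate_gene_trees_and_alignments(
    config: SimulationConfig, species_tree: dendropy.Tree,
    group_map: GroupMap | None = None,
) -> tuple[dict[str, dendropy.Tree], dict[str, Alignment], dict[str, frozenset | None]]:
    """Per-gene perturbed trees, evolved alignments, and perturbation records.

    Each gene is the species tree with, at probability ``discordance_prob``,
    exactly one NNI at a uniformly chosen eligible internal edge; by default
    the inter-domain edge is never perturbed, so every gene recovers the
    deep split.
    """
    config.validate()
    taxa = frozenset(leaf_labels(species_tree))
    if len(taxa) < 4:
        raise InputError("species tree has <4 leaves: no internal edge to perturb")
    excluded: set[frozenset] = set()
    if config.exclude_interdomain and group_map is not None:
        excluded.add(interdomain_bipartition(group_map))
    rng = stage_rng(config.seed, "genes")

    gene_trees: dict[str, dendropy.Tree] = {}
    alignments: dict[str, Alignment] = {}
    perturbations: dict[str, frozenset | None] = {}
    for g in range(1, config.n_universal_genes + 1):
        gene = f"gene{g:03d}"
        tree = dendropy.Tree(species_tree)
        destroyed: frozenset | None = None
        if rng.random() < config.discordance_prob:
            eligible = [
                n for n in _internal_nonroot_nodes(tree)
                if _node_bipartition(n, taxa) not in excluded
            ]
            if not eligible:
                raise InputError("no eligible internal edge for perturbation")
            node = eligible[int(rng.integers(len(eligible)))]
            destroyed = apply_nni(tree, node, rng)
        rows = evolve_sequences(tree, config.sites_per_gene, rng,
                                config.background_c_freq)
        gene_trees[gene] = tree
        alignments[gene] = Alignment({t: rows[t] for t in sorted(rows)})
        perturbations[gene] = destroyed
    return gene_trees, alignments, perturbations


def n_eligible_edges(species_tree: dendropy.Tree,
                     group_map: GroupMap | None = None,
                     exclude_interdomain: bool = True) -> int:
    """Number of internal edges the discordance model may perturb."""
    taxa = frozenset(leaf_labels(species_tree))
    excluded: set[frozenset] = set()
    if exclude_interdomain and group_map is not None:
        excluded.add(interdomain_bipartition(group_map))
    return sum(
        1 for n in _internal_nonroot_nodes(species_tree)
        if _node_bipartition(n, taxa) not in excluded
    )


# ---------------------------------------------------------------------------
# Proteomes with planted motifs
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int,
                    c_freq: float) -> np.ndarray:
    probs = np.full(20, (1.0 - c_freq) / 19.0)
    probs[_C_INDEX] = c_freq
    return rng.choice(20, size=length, p=probs)


def _plant_motif(seq: np.ndarray, pos0: int, pattern: MotifPattern,
                 rng: np.random.Generator) -> None:
    """Overwrite a window with one motif instance (spacers never C)."""
    offsets = np.cumsum([0, pattern.spacers[0] + 1, pattern.spacers[1] + 1,
                         pattern.spacers[2] + 1])
    window = _NON_C[rng.integers(0, 19, size=pattern.length)]
    window[offsets] = _C_INDEX
    seq[pos0:pos0 + pattern.length] = window


def simulate_proteomes(config: SimulationConfig, group_map: GroupMap,
                       pattern: MotifPattern = GENERAL_PATTERN,
                       ) -> tuple[dict[str, dict[str, str]], list[tuple[str, str, int]]]:
    """Per-genome proteomes with motif instances planted at rate ``motif_rate``.

    Returns ``(proteomes, plantings)`` where plantings are (genome, protein,
    1-based position) records.
    """
    config.validate()
    if not len(group_map):
        raise InputError("group map is empty")
    if config.motif_rate > 0 and config.protein_length < pattern.length:
        raise ConfigError(
            f"protein_length: {config.protein_length} shorter than the "
            f"{pattern.length}-residue motif"
        )
    rng = stage_rng(config.seed, "proteomes")
    proteomes: dict[str, dict[str, str]] = {}
    plantings: list[tuple[str, str, int]] = []
    for genome in group_map.genomes():
        prots: dict[str, str] = {}
        for p in range(1, config.proteins_per_genome + 1):
            prot_id = f"{genome}_p{p:04d}"
            seq = _random_protein(rng, config.protein_length,
                                  config.background_c_freq)
            if rng.random() < config.motif_rate:
                pos0 = int(rng.integers(0, config.protein_length - pattern.length + 1))
                _plant_motif(seq, pos0, pattern, rng)
                plantings.append((genome, prot_id, pos0 + 1))
            prots[prot_id] = _AA[seq].tobytes().decode()
        proteomes[genome] = prots
    return proteomes, plantings


# ---------------------------------------------------------------------------
# Ortholog families with controlled presence and identity
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, fraction: float,
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    n_mut = int(round(fraction * len(seq)))
    if n_mut:
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 20, size=n_mut)) % 20
    return out


def simulate_families(config: SimulationConfig, group_map: GroupMap,
                      ) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """Ortholog families with known group presence and identity structure.

    Each family is present in a controlled set of groups (one member genome
    per present group).  Members diverge ~``member_divergence`` from a family
    ancestor, so all pairs stay far above the 30% identity criterion; a
    ``diverged_family_fraction`` of multi-member families instead contains
    one member randomized at ``diverged_divergence``, pushing at least one
    pair far below it.  Ground truth records presence vectors and the
    intended retained set.
    """
    config.validate()
    rng = stage_rng(config.seed, "families")
    groups = group_map.groups(ARCHAEBACTERIA) + group_map.groups(EUBACTERIA)
    if config.family_presence_probs is not None:
        fpp = np.asarray(config.family_presence_probs, dtype=float)
    else:
        base = rng.uniform(0.15, 0.95, size=config.n_families)
        fpp = np.repeat(base[:, None], len(groups), axis=1)

    truth = GroundTruth()
    rows = []
    sequences: dict[str, str] = {}
    for f in range(config.n_families):
        fam = f"fam{f + 1:04d}"
        present = [g for k, g in enumerate(groups) if rng.random() < fpp[f, k]]
        if not present:
            present = [groups[int(rng.integers(len(groups)))]]
        members = []
        for group in present:
            candidates = group_map.genomes_in_group(group)
            members.append(candidates[int(rng.integers(len(candidates)))])
        ancestor = rng.integers(0, 20, size=config.family_seq_length)
        diverged_idx = -1
        if len(members) >= 2 and rng.random() < config.diverged_family_fraction:
            diverged_idx = int(rng.integers(len(members)))
        annotation = f"COG{3000 + f:04d} (S) synthetic family {f + 1}"
        for m, genome in enumerate(members):
            frac = (config.diverged_divergence if m == diverged_idx
                    else config.member_divergence)
            seq = _mutate(ancestor, frac, rng)
            prot_id = f"{fam}_{genome}"
            sequences[prot_id] = _AA[seq].tobytes().decode()
            rows.append({
                "family_id": fam, "genome_id": genome,
                "protein_id": prot_id, "annotation": annotation,
            })
        truth.family_presence[fam] = set(present)
        if diverged_idx < 0:
            truth.family_retained.add(fam)
    families = pd.DataFrame(rows, columns=["family_id", "genome_id",
                                           "protein_id", "annotation"])
    return families, sequences, truth


# ---------------------------------------------------------------------------
# Similarity hit tables
# ---------------------------------------------------------------------------

def _hit_row(rng: np.random.Generator, gene: str, genome: str, counter: int,
             evalue: float, pident: float) -> dict:
    length = int(rng.integers(150, 400))
    return {
        "qseqid": gene,
        "sseqid": f"{genome}|hit{counter:05d}",
        "pident": round(pident, 2),
        "length": length,
        "mismatch": int(round(length * (100.0 - pident) / 100.0)),
        "gapopen": int(rng.integers(0, 4)),
        "qstart": 1, "qend": length, "sstart": 1, "send": length,
        "evalue": evalue,
        "bitscore": round(float(rng.uniform(50, 900)), 1),
    }


def simulate_hit_table(config: SimulationConfig, group_map: GroupMap,
                       pathways: Mapping[str, PathwayDef] = DEFAULT_PATHWAYS,
                       marker_sets: Mapping[str, frozenset] = DEFAULT_MARKER_SETS,
                       cd1_gene: str = CD1_GENE,
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """12-column hit table realizing a known per-genome pathway truth.

    For each genome and pathway, passing hits (E well below 1e-10, identity
    well above 25) are emitted for exactly the slot fraction the truth
    dictates; decoy hits each fail exactly one filter.  cd1 nitrite
    reductase and marker-complex (HdrABC/QmoABC) placements are seeded with
    their own probabilities and recorded in the truth.
    """
    config.validate()
    for name, pw in pathways.items():
        if pw.n_slots == 0:
            raise ConfigError(f"pathway {name!r} has zero gene slots")
    rng = stage_rng(config.seed, "hits")
    truth = GroundTruth()
    rows: list[dict] = []
    counter = 0

    def passing(gene: str, genome: str) -> dict:
        nonlocal counter
        counter += 1
        return _hit_row(rng, gene, genome, counter,
                        evalue=10.0 ** float(rng.uniform(-40, -15)),
                        pident=float(rng.uniform(30.0, 95.0)))

    for genome in group_map.genomes():
        for name in sorted(pathways):
            pw = pathways[name]
            if config.pathway_truth is not None:
                c = config.pathway_truth.get(genome, {}).get(name)
                if c is None:
                    raise ConfigError(
                        f"pathway_truth: no completeness for {genome}/{name}"
                    )
                n_pass = int(round(c * pw.n_slots))
            else:
                n_pass = int(rng.integers(0, pw.n_slots + 1))
            truth.pathway_completeness[(genome, name)] = n_pass / pw.n_slots
            slot_idx = sorted(rng.choice(pw.n_slots, size=n_pass, replace=False))
            for s in slot_idx:
                members = sorted(pw.slots[s])
                gene = members[int(rng.integers(len(members)))]
                rows.append(passing(gene, genome))
        if rng.random() < config.cd1_prob:
            truth.cd1_genomes.add(genome)
            rows.append(passing(cd1_gene, genome))
        for complex_name in sorted(marker_sets):
            if rng.random() < config.marker_prob:
                truth.marker_taxa.add(group_map.group_of(genome))
                subunits = sorted(marker_sets[complex_name])
                n_sub = int(rng.integers(1, len(subunits) + 1))
                for gene in sorted(rng.choice(subunits, size=n_sub, replace=False)):
                    rows.append(passing(gene, genome))
        all_genes = sorted({g for pw in pathways.values() for g in pw.genes})
        for k in range(config.decoys_per_genome):
            counter += 1
            gene = all_genes[int(rng.integers(len(all_genes)))]
            if k % 2 == 0:  # fails the E-value filter only
                rows.append(_hit_row(
                    rng, gene, genome, counter,
                    evalue=10.0 ** float(rng.uniform(-9, -3)),
                    pident=float(rng.uniform(30.0, 95.0))))
            else:  # fails the identity filter only
                rows.append(_hit_row(
                    rng, gene, genome, counter,
                    evalue=10.0 ** float(rng.uniform(-40, -15)),
                    pident=float(rng.uniform(5.0, 24.5))))
    hits = pd.DataFrame(rows)
    hits["genome_id"] = hits["sseqid"].str.split("|").str[0]
    return hits, truth


# ---------------------------------------------------------------------------
# Full pipeline run with on-disk outputs
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig, outdir: str | Path,
                   ) -> tuple[GroupMap, GroundTruth]:
    """Run every generator stage and write all outputs under ``outdir``.

    Layout: ``group_map.tsv``, ``species_tree.nwk``, ``gene_trees/``,
    ``alignments/``, ``proteomes/``, ``families.tsv``,
    ``family_seqs.fasta``, ``hits.tsv``, ``truth/``, ``config.yaml``.
    Byte-identical across runs with the same config.
    """
    config.validate()
    outdir = Path(outdir)
    for sub in ("gene_trees", "alignments", "proteomes", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    group_map, species_tree = simulate_taxonomy(config)
    group_map.write_tsv(outdir / "group_map.tsv")
    write_newick(species_tree, outdir / "species_tree.nwk")

    gene_trees, alignments, perturbations = simulate_gene_trees_and_alignments(
        config, species_tree, group_map)
    for gene in sorted(gene_trees):
        write_newick(gene_trees[gene], outdir / "gene_trees" / f"{gene}.nwk")
        alignments[gene].to_fasta(outdir / "alignments" / f"{gene}.fasta")

    proteomes, plantings = simulate_proteomes(config, group_map)
    for genome, prots in proteomes.items():
        write_fasta(outdir / "proteomes" / f"{genome}.fasta", prots.items())

    families, fam_seqs, fam_truth = simulate_families(config, group_map)
    write_family_table(families, outdir / "families.tsv")
    write_fasta(outdir / "family_seqs.fasta", sorted(fam_seqs.items()))

    hits, hit_truth = simulate_hit_table(config, group_map)
    write_hit_table(hits, outdir / "hits.tsv")

    truth = GroundTruth(
        species_tree_newick=(outdir / "species_tree.nwk").read_text(),
        gene_perturbations=perturbations,
        motif_plantings=plantings,
        family_presence=fam_truth.family_presence,
        family_retained=fam_truth.family_retained,
        pathway_completeness=hit_truth.pathway_completeness,
        cd1_genomes=hit_truth.cd1_genomes,
        marker_taxa=hit_truth.marker_taxa,
    )
    _write_truth(truth, outdir / "truth")
    (outdir / "config.yaml").write_text(config.to_yaml())
    return group_map, truth


def _write_truth(truth: GroundTruth, truth_dir: Path) -> None:
    pd.DataFrame(
        [{"gene": g, "destroyed_bipartition":
          ";".join(sorted(b)) if b else ""}
         for g, b in sorted(truth.gene_perturbations.items())],
        columns=["gene", "destroyed_bipartition"],
    ).to_csv(truth_dir / "gene_perturbations.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.motif_plantings),
        columns=["genome_id", "protein_id", "position"],
    ).to_csv(truth_dir / "motif_plantings.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"family_id": f, "groups": ";".join(sorted(gs)),
          "retained": f in truth.family_retained}
         for f, gs in sorted(truth.family_presence.items())],
        columns=["family_id", "groups", "retained"],
    ).to_csv(truth_dir / "family_presence.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"genome_id": g, "pathway": p, "completeness": c}
         for (g, p), c in sorted(truth.pathway_completeness.items())],
        columns=["genome_id", "pathway", "completeness"],
    ).to_csv(truth_dir / "pathway_truth.tsv", sep="\t", index=False,
             float_format="%.6f")
    pd.DataFrame({"genome_id": sorted(truth.cd1_genomes)}).to_csv(
        truth_dir / "cd1_genomes.tsv", sep="\t", index=False)
    pd.DataFrame({"taxon": sorted(truth.marker_taxa)}).to_csv(
        truth_dir / "marker_taxa.tsv", sep="\t", index=False)
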