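"""Cross-domain gene-family stringency analysis.

Ortholog families are filtered by a pairwise-identity criterion (all member
pairs >= 30% identical by default, because alignment and phylogeny degrade
badly below that), their group-level presence is counted per domain, and a
stringency grid tabulates how many families are jointly present in at least
``a`` of the archaebacterial groups and at least ``b`` of the eubacterial
groups, for descending threshold ladders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, InputError
from .io import ARCHAEBACTERIA, EUBACTERIA, GroupMap

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str,
                      denominator: str = "alignment") -> float:
    """Global-alignment percent identity between two protein sequences.

    Needleman–Wunsch with BLOSUM62 scoring and affine gaps (-11 open,
    -1 extend).  With ``denominator="alignment"`` (default) identity is
    100 x identical aligned pairs / alignment columns after trimming
    terminal-gap columns; with ``denominator="shorter"`` the shorter
    sequence's length is used instead.  The two sequences are canonically
    ordered before aligning so the result is exactly symmetric.
    """
    if denominator not in ("alignment", "shorter"):
        raise ConfigError("denominator: must be 'alignment' or 'shorter'")
    if not seq_a or not seq_b:
        raise InputError("pairwise_identity: empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_b < seq_a:  # canonical order => symmetry under co-optimal alignments
        seq_a, seq_b = seq_b, seq_a
    aln = _aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim terminal-gap columns from both ends
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    matches = sum(
        1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-"
    )
    n = min(len(seq_a), len(seq_b)) if denominator == "shorter" else end - start
    if n == 0:
        return 0.0
    return 100.0 * matches / n


def family_members(families: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    """Family table -> ``{family_id: [(genome_id, protein_id), ...]}``."""
    out: dict[str, list[tuple[str, str]]] = {}
    for row in families.itertuples():
        out.setdefault(row.family_id, []).append((row.genome_id, row.protein_id))
    return out


def filter_families_by_identity(families: pd.DataFrame,
                                sequences: Mapping[str, str],
                                min_identity: float = 30.0,
                                max_family_size: int = 100) -> pd.DataFrame:
    """Retain families whose members are ALL pairwise >= ``min_identity``.

    ``sequences`` maps protein_id -> sequence.  Single-member families pass
    trivially.  All-pairs alignment is O(n^2) per family, so families larger
    than ``max_family_size`` raise rather than being silently subsampled.
    """
    keep: set[str] = set()
    for fam, members in family_members(families).items():
        if len(members) > max_family_size:
            raise InputError(
                f"family {fam!r}: {len(members)} members exceeds "
                f"max_family_size={max_family_size}"
            )
        seqs = []
        for genome, prot in members:
            if prot not in sequences:
                raise InputError(
                    f"family {fam!r}: no sequence for member {genome}/{prot}"
                )
            seqs.append(sequences[prot])
        ok = all(
            pairwise_identity(seqs[i], seqs[j]) >= min_identity
            for i in range(len(seqs)) for j in range(i + 1, len(seqs))
        )
        if ok:
            keep.add(fam)
    return families[families["family_id"].isin(keep)]


def group_presence(families: pd.DataFrame, group_map: GroupMap) -> pd.DataFrame:
    """Per-family count of distinct archaebacterial / eubacterial groups hit.

    A group counts as hit when >=1 member genome belongs to it; multiple
    members in one group count once.
    """
    group_map.require(families["genome_id"], context="family table")
    rows = []
    for fam, members in sorted(family_members(families).items()):
        arch_groups: set[str] = set()
        eub_groups: set[str] = set()
        for genome, _prot in members:
            domain, group = group_map.mapping[genome]
            (arch_groups if domain == ARCHAEBACTERIA else eub_groups).add(group)
        rows.append({
            "family_id": fam,
            "n_arch_groups": len(arch_groups),
            "n_eub_groups": len(eub_groups),
        })
    return pd.DataFrame(rows, columns=["family_id", "n_arch_groups", "n_eub_groups"])


@dataclass
class StringencyGrid:
    """Counts of families jointly meeting (arch >= a) AND (eub >= b) thresholds.

    ``counts`` is indexed by archaebacterial threshold (rows, descending) and
    eubacterial threshold (columns, descending); ``families`` holds the
    per-cell family-id lists for Table-2-style reporting.
    """

    counts: pd.DataFrame
    families: dict[tuple[int, int], list[str]]

    def cell(self, arch: int, eub: int) -> int:
        return int(self.counts.loc[arch, eub])

    def check_monotone(self) -> None:
        """Counts must not decrease as either threshold relaxes."""
        c = self.counts.to_numpy()
        if (c[:, 1:] < c[:, :-1]).any() or (c[1:, :] < c[:-1, :]).any():
            raise AssertionError("stringency grid is not monotone")


def stringency_grid(presence: pd.DataFrame,
                    arch_thresholds: Sequence[int] = (11, 10, 9, 8),
                    eub_thresholds: Sequence[int] = (30, 25, 20, 15, 10, 5, 2),
                    n_arch_groups: int | None = None,
                    n_eub_groups: int | None = None) -> StringencyGrid:
    """Build the joint-presence stringency grid from per-family group counts."""
    for label, thresholds, total in (
        ("arch", arch_thresholds, n_arch_groups),
        ("eub", eub_thresholds, n_eub_groups),
    ):
        if any(t <= 0 for t in thresholds):
            raise ConfigError(f"{label} thresholds must be positive")
        if total is not None and any(t > total for t in thresholds):
            raise ConfigError(
                f"{label} threshold exceeds the {total} available groups"
            )
    arch_thresholds = sorted(set(arch_thresholds), reverse=True)
    eub_thresholds = sorted(set(eub_thresholds), reverse=True)
    counts = pd.DataFrame(0, index=arch_thresholds, columns=eub_thresholds)
    counts.index.name = "arch_min_groups"
    counts.columns.name = "eub_min_groups"
    cell_families: dict[tuple[int, int], list[str]] = {}
    for a in arch_thresholds:
        for b in eub_thresholds:
            hit = presence[(presence["n_arch_groups"] >= a)
                           & (presence["n_eub_groups"] >= b)]
            fams = sorted(hit["family_id"])
            counts.loc[a, b] = len(fams)
            cell_families[(a, b)] = fams
    grid = StringencyGrid(counts, cell_families)
    grid.check_monotone()
    return grid


def cell_report(grid: StringencyGrid, families: pd.DataFrame,
                arch: int, eub: int) -> pd.DataFrame:
    """Annotation listing (family_id, annotation) for one grid cell."""
    fams = grid.families[(arch, eub)]
    ann = (
        families.drop_duplicates("family_id")
        .set_index("family_id")["annotation"]
    )
    return pd.DataFrame({
        "family_id": fams,
        "annotation": [ann.get(f, "") for f in fams],
    })
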