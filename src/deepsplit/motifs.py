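"""Census of 4Fe-4S cluster-forming cysteine motifs across proteomes.

The general motif is the ferredoxin-type cysteine spacing C-x(2)-C-x(2)-C-x(3)-C
whose four thiols ligate a cubane [4Fe-4S] cluster.  A census counts, per
genome, the proportion of proteins containing the general motif and the
absolute number of proteins containing each of a configurable set of variant
spacings.  A separate step flags taxa in which electron-bifurcation marker
complexes (HdrABC, QmoABC) are detected.

Variant spacer triples default to (2,2,2), (2,3,3), (3,2,3) and (2,2,4);
these defaults are placeholders for "additional motifs with different
numbers of bridging amino acids" and are fully configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError
from .io import GroupMap, read_fasta

#: 20 standard amino acids; X is tolerated in input but never matches a
#: fixed cysteine position.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class MotifPattern:
    """Cysteine motif C-x(i)-C-x(j)-C-x(k)-C defined by its spacer triple."""

    spacers: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacers) != 3 or any(s < 0 for s in self.spacers):
            raise ConfigError(f"spacers: need 3 non-negative ints, got {self.spacers}")

    @property
    def length(self) -> int:
        return 4 + sum(self.spacers)

    @property
    def name(self) -> str:
        i, j, k = self.spacers
        return f"CX{i}CX{j}CX{k}C"

    @property
    def regex(self) -> re.Pattern:
        i, j, k = self.spacers
        # lookahead so overlapping occurrences are all reported
        return re.compile(f"(?=C.{{{i}}}C.{{{j}}}C.{{{k}}}C)")


#: The general 4Fe-4S ferredoxin motif, C-x(2)-C-x(2)-C-x(3)-C.
GENERAL_PATTERN = MotifPattern((2, 2, 3))

#: Placeholder variant spacings (configurable).
DEFAULT_VARIANTS = (
    MotifPattern((2, 2, 2)),
    MotifPattern((2, 3, 3)),
    MotifPattern((3, 2, 3)),
    MotifPattern((2, 2, 4)),
)

#: Electron-bifurcation marker complexes: any subunit hit flags the taxon
#: under the default (lenient) rule.
DEFAULT_MARKER_SETS: dict[str, frozenset[str]] = {
    "HdrABC": frozenset({"HdrA", "HdrB", "HdrC"}),
    "QmoABC": frozenset({"QmoA", "QmoB", "QmoC"}),
}


def _validate_sequence(seq: str, record: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise InputError(
            f"record {record!r}: invalid residue(s) {''.join(sorted(bad))} "
            "(expected the 20 IUPAC amino acids, X tolerated)"
        )
    return seq


def scan_protein(sequence: str, pattern: MotifPattern = GENERAL_PATTERN,
                 record: str = "<sequence>") -> list[int]:
    """Return all 1-based start positions of ``pattern`` in ``sequence``.

    Overlapping occurrences are all reported.  Spacer positions match any
    residue (including X); the four fixed positions match only C.
    """
    seq = _validate_sequence(sequence, record)
    if len(seq) < pattern.length:
        return []
    return [m.start() + 1 for m in pattern.regex.finditer(seq)]


@dataclass
class MotifCensusRow:
    """Per-genome motif census: general-motif proportion and variant counts."""

    genome_id: str
    n_proteins: int
    n_matching_general: int
    variant_counts: dict[str, int]

    @property
    def proportion_general(self) -> float:
        return self.n_matching_general / self.n_proteins


def census_genome(genome_id: str, proteome: Mapping[str, str],
                  general: MotifPattern = GENERAL_PATTERN,
                  variants: Sequence[MotifPattern] = DEFAULT_VARIANTS,
                  ) -> MotifCensusRow:
    """Census one genome: each protein counts at most once per pattern."""
    if not proteome:
        raise InputError(f"genome {genome_id!r}: empty proteome, proportion undefined")
    n_general = 0
    variant_counts = {p.name: 0 for p in variants}
    for prot_id, seq in proteome.items():
        rec = f"{genome_id}/{prot_id}"
        if scan_protein(seq, general, record=rec):
            n_general += 1
        for pat in variants:
            if scan_protein(seq, pat, record=rec):
                variant_counts[pat.name] += 1
    return MotifCensusRow(genome_id, len(proteome), n_general, variant_counts)


def census_proteomes(proteomes: Mapping[str, Mapping[str, str]],
                     general: MotifPattern = GENERAL_PATTERN,
                     variants: Sequence[MotifPattern] = DEFAULT_VARIANTS,
                     ) -> pd.DataFrame:
    """Census many genomes into a tidy table, one row per genome."""
    rows = []
    for genome_id in sorted(proteomes):
        row = census_genome(genome_id, proteomes[genome_id], general, variants)
        rec = {
            "genome_id": row.genome_id,
            "n_proteins": row.n_proteins,
            "n_matching_general": row.n_matching_general,
            "proportion_general": row.proportion_general,
        }
        rec.update(row.variant_counts)
        rows.append(rec)
    return pd.DataFrame(rows)


def census_directory(proteome_dir: str | Path, **kwargs) -> pd.DataFrame:
    """Census every ``*.fasta``/``*.faa`` file in a directory (stem = genome id)."""
    proteome_dir = Path(proteome_dir)
    proteomes = {}
    for path in sorted(proteome_dir.iterdir()):
        if path.suffix.lower() in {".fasta", ".faa", ".fa"}:
            proteomes[path.stem] = read_fasta(path)
    if not proteomes:
        raise InputError(f"{proteome_dir}: no FASTA proteomes found")
    return census_proteomes(proteomes, **kwargs)


def flag_markers(hits: pd.DataFrame, group_map: GroupMap,
                 marker_sets: Mapping[str, Iterable[str]] = DEFAULT_MARKER_SETS,
                 e_max: float = 1e-10, min_identity: float = 25.0,
                 strict: bool = False) -> pd.DataFrame:
    """Flag taxa (groups) containing electron-bifurcation marker complexes.

    Default (lenient) rule: a taxon is flagged if any of its genomes has a
    passing hit to any subunit of any marker complex.  With ``strict=True``
    a taxon is flagged only if some single genome carries passing hits to
    every subunit of at least one complex.
    """
    if not marker_sets or any(not set(s) for s in marker_sets.values()):
        raise ConfigError("marker_sets: need at least one non-empty subunit set")
    all_subunits = {g for s in marker_sets.values() for g in s}
    relevant = hits[hits["qseqid"].isin(all_subunits)]
    passing = relevant[(relevant["evalue"] <= e_max)
                       & (relevant["pident"] >= min_identity)]
    group_map.require(passing["genome_id"], context="marker hits")

    flagged: set[str] = set()
    if strict:
        by_genome = passing.groupby("genome_id")["qseqid"].agg(set)
        for genome, genes in by_genome.items():
            if any(set(subunits) <= genes for subunits in marker_sets.values()):
                flagged.add(group_map.group_of(genome))
    else:
        for genome in passing["genome_id"].unique():
            flagged.add(group_map.group_of(genome))
    rows = [{"taxon": t, "flagged": t in flagged} for t in group_map.groups()]
    return pd.DataFrame(rows, columns=["taxon", "flagged"])
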