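"""Presence calling for quinone and haem biosynthesis pathways.

Similarity-search hits (12-column tabular) are filtered (E-value <= 1e-10 and
percent identity >= 25 by default), scored per genome as the fraction of
pathway gene *slots* with at least one retained hit, and a pathway is called
present when completeness reaches 70%.  A slot is a set of interchangeable
genes (e.g. ubiD/ubiX: either satisfies the slot), so slash pairs are not
double-counted.  One documented exception: in genomes that also carry cd1
nitrite reductase — the only enzyme containing haem d1 — a passing
alternative-haem call is reassigned to haem d1 biosynthesis and reported as
absent with ``d1_reassigned=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, InputError
from .io import GroupMap

HAEM_ALTERNATIVE = "haem_alternative"

#: Query gene name used to detect cd1 nitrite reductase in the hit table.
CD1_GENE = "NirS_cd1"


@dataclass(frozen=True)
class PathwayDef:
    """A pathway as an ordered tuple of gene slots.

    Each slot is a frozenset of interchangeable gene names; a hit to any
    member satisfies the slot.
    """

    name: str
    slots: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise ConfigError(f"pathway {self.name!r}: needs at least one slot")
        seen: set[str] = set()
        for slot in self.slots:
            if not slot:
                raise ConfigError(f"pathway {self.name!r}: empty gene slot")
            if seen & slot:
                raise ConfigError(
                    f"pathway {self.name!r}: gene repeated across slots: "
                    f"{sorted(seen & slot)}"
                )
            seen |= slot

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for slot in self.slots for g in slot)


def _pw(name: str, *slots: str | tuple[str, ...]) -> PathwayDef:
    return PathwayDef(name, tuple(
        frozenset([s]) if isinstance(s, str) else frozenset(s) for s in slots
    ))


#: Default pathway definitions (slash pairs share one slot).
DEFAULT_PATHWAYS: dict[str, PathwayDef] = {p.name: p for p in (
    _pw("ubiquinone", "ubiC", "ubiA", ("ubiD", "ubiX"), "ubiB",
        "ubiH", "ubiE", "ubiF", "ubiG"),
    _pw("menaquinone_alternative", "MqnA", "MqnB", "MqnC", "MqnD"),
    _pw("menaquinone_classical", "MenF", "MenD", "MenH", "MenC",
        "MenE", "MenB", "MenA", ("UbiE", "MenG")),
    _pw("haem_classical", "HemE", ("HemF", "HemN"), ("HemY", "HemG"), "HemH"),
    _pw(HAEM_ALTERNATIVE, "AhbA", "AhbB", "AhbC", "AhbD"),
)}


def load_pathways(path: str | Path) -> dict[str, PathwayDef]:
    """Load pathway definitions from YAML: ``{name: [[genes...], ...]}``."""
    raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, PathwayDef] = {}
    for name, slots in raw.items():
        out[name] = PathwayDef(str(name), tuple(
            frozenset([slot]) if isinstance(slot, str) else frozenset(map(str, slot))
            for slot in slots
        ))
    return out


def filter_hits(hits: pd.DataFrame, e_max: float = 1e-10,
                min_identity: float = 25.0) -> pd.DataFrame:
    """Retain hits with E-value <= ``e_max`` and identity >= ``min_identity``.

    Both bounds are inclusive; input row order is preserved.  Idempotent.
    """
    if e_max <= 0 or min_identity <= 0:
        raise ConfigError("filter thresholds must be positive")
    mask = (hits["evalue"] <= e_max) & (hits["pident"] >= min_identity)
    return hits[mask]


def completeness(genome_hits: pd.DataFrame, pathway: PathwayDef) -> float:
    """Fraction of pathway slots with >=1 retained hit to any member gene.

    Expects already-filtered hits for a single genome; multiple hits to one
    slot count once.  No hits at all gives 0.0.
    """
    genes_hit = set(genome_hits["qseqid"].unique())
    satisfied = sum(1 for slot in pathway.slots if slot & genes_hit)
    return satisfied / pathway.n_slots


def completeness_table(filtered_hits: pd.DataFrame,
                       pathways: Mapping[str, PathwayDef],
                       genomes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-genome, per-pathway completeness (tidy: genome_id, pathway, completeness)."""
    if genomes is None:
        genomes = sorted(filtered_hits["genome_id"].unique())
    else:
        genomes = sorted(genomes)
    by_genome = dict(tuple(filtered_hits.groupby("genome_id")))
    empty = filtered_hits.iloc[0:0]
    rows = []
    for genome in genomes:
        ghits = by_genome.get(genome, empty)
        for name in sorted(pathways):
            rows.append({
                "genome_id": genome,
                "pathway": name,
                "completeness": completeness(ghits, pathways[name]),
            })
    return pd.DataFrame(rows, columns=["genome_id", "pathway", "completeness"])


def cd1_positive_genomes(filtered_hits: pd.DataFrame,
                         cd1_gene: str = CD1_GENE) -> set[str]:
    """Genomes with >=1 retained hit to the cd1 nitrite reductase query."""
    return set(filtered_hits.loc[filtered_hits["qseqid"] == cd1_gene, "genome_id"])


def call_pathways(completeness_df: pd.DataFrame, cd1_genomes: set[str],
                  threshold: float = 0.70,
                  known_pathways: Iterable[str] | None = None) -> pd.DataFrame:
    """Turn completeness fractions into presence calls.

    present <=> completeness >= threshold, except that an above-threshold
    alternative-haem call in a cd1-positive genome is reassigned to haem d1
    biosynthesis (present=False, d1_reassigned=True).
    """
    if known_pathways is not None:
        unknown = set(completeness_df["pathway"]) - set(known_pathways)
        if unknown:
            raise InputError(f"unknown pathway name(s): {sorted(unknown)}")
    calls = completeness_df.copy()
    calls["present"] = calls["completeness"] >= threshold
    calls["d1_reassigned"] = False
    reassign = (
        (calls["pathway"] == HAEM_ALTERNATIVE)
        & calls["present"]
        & calls["genome_id"].isin(cd1_genomes)
    )
    calls.loc[reassign, "present"] = False
    calls.loc[reassign, "d1_reassigned"] = True
    return calls


def aggregate_by_taxon(calls: pd.DataFrame, group_map: GroupMap) -> pd.DataFrame:
    """Per-taxon, per-pathway proportion of genomes called present.

    Every genome in ``calls`` must be mapped; taxa with zero genomes in the
    group map are excluded with a warning.
    """
    group_map.require(calls["genome_id"], context="pathway calls")
    df = calls.copy()
    df["taxon"] = df["genome_id"].map(group_map.group_of)
    wide = (
        df.groupby(["taxon", "pathway"])["present"].mean()
        .unstack("pathway").sort_index()
    )
    empty_taxa = sorted(set(group_map.groups()) - set(wide.index))
    if empty_taxa:
        warnings.warn(
            f"taxa with no called genomes excluded: {', '.join(empty_taxa)}",
            stacklevel=2,
        )
    return wide


def run_pathway_calling(hits: pd.DataFrame, group_map: GroupMap,
                        pathways: Mapping[str, PathwayDef] = DEFAULT_PATHWAYS,
                        e_max: float = 1e-10, min_identity: float = 25.0,
                        threshold: float = 0.70, cd1_gene: str = CD1_GENE,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Fig-7-style pipeline: filter, score, call, aggregate.

    Returns ``(calls, taxon_matrix)``.
    """
    filtered = filter_hits(hits, e_max=e_max, min_identity=min_identity)
    comp = completeness_table(filtered, pathways, genomes=group_map.genomes())
    calls = call_pathways(comp, cd1_positive_genomes(filtered, cd1_gene),
                          threshold=threshold, known_pathways=pathways)
    taxa = aggregate_by_taxon(calls, group_map)
    return calls, taxa
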