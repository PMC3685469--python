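"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: FASTA (proteomes, alignments, sequence stores), Newick (trees),
TSV (genome->group maps, ortholog family tables) and 12-column tabular
similarity-search hit files.  All writers are deterministic: fixed column
order, fixed float formatting, fixed 60-column FASTA wrapping, so that two
runs from the same seed produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import pandas as pd

from .errors import InputError, ParseError

ARCHAEBACTERIA = "archaebacteria"
EUBACTERIA = "eubacteria"
DOMAINS = (ARCHAEBACTERIA, EUBACTERIA)

#: Column names of the 12-column tabular similarity-search format.
HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass
class GroupMap:
    """Genome -> (domain, taxonomic group) assignment for two domains.

    The two domains are ``archaebacteria`` and ``eubacteria``; groups are
    higher taxa (phylum-level in the real data) used for presence counting
    and per-taxon aggregation.
    """

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genome, (domain, _group) in self.mapping.items():
            if domain not in DOMAINS:
                raise InputError(
                    f"genome {genome!r}: unknown domain {domain!r} "
                    f"(expected one of {DOMAINS})"
                )

    def __contains__(self, genome: str) -> bool:
        return genome in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def genomes(self, domain: str | None = None) -> list[str]:
        if domain is None:
            return sorted(self.mapping)
        return sorted(g for g, (d, _) in self.mapping.items() if d == domain)

    def groups(self, domain: str | None = None) -> list[str]:
        return sorted({
            grp for _, (d, grp) in self.mapping.items()
            if domain is None or d == domain
        })

    def genomes_in_group(self, group: str) -> list[str]:
        return sorted(g for g, (_, grp) in self.mapping.items() if grp == group)

    def domain_of(self, genome: str) -> str:
        return self.mapping[genome][0]

    def group_of(self, genome: str) -> str:
        return self.mapping[genome][1]

    def require(self, genomes: Iterable[str], context: str = "input") -> None:
        """Raise :class:`InputError` listing any genome absent from the map."""
        missing = sorted(set(genomes) - set(self.mapping))
        if missing:
            raise InputError(
                f"{context}: genomes absent from group map: {', '.join(missing)}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": g, "domain": d, "group": grp}
            for g, (d, grp) in sorted(self.mapping.items())
        ]
        return pd.DataFrame(rows, columns=["genome_id", "domain", "group"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"genome_id", "domain", "group"}
        if not required.issubset(df.columns):
            raise ParseError(
                f"{path}: group map needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        dup = df["genome_id"][df["genome_id"].duplicated()]
        if not dup.empty:
            raise InputError(
                f"{path}: duplicate genome ids: {', '.join(sorted(set(dup)))}"
            )
        return cls({
            r.genome_id: (r.domain, r.group) for r in df.itertuples()
        })


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` records from a FASTA file."""
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path, allow_duplicates: bool = False) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered ``{id: sequence}`` dict."""
    records: dict[str, str] = {}
    for name, seq in iter_fasta(path):
        if name in records and not allow_duplicates:
            raise InputError(f"{path}: duplicate sequence id {name!r}")
        records[name] = seq
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick (dendropy-backed; underscores in labels are preserved verbatim)
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read one Newick tree from a path or a literal Newick string."""
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise InputError(f"duplicate leaf labels in Newick input: {exc}") from None
    except dendropy.utility.error.DataParseError as exc:
        raise ParseError(f"malformed Newick input: {exc}") from None


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# 12-column tabular hit files
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tabular hit file.

    Subject ids of the form ``genome|protein`` are split into a
    ``genome_id`` column; a plain subject id is used as its own genome id.
    Raises :class:`ParseError` with the 1-based line number on malformed rows.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                row = {
                    "qseqid": fields[0],
                    "sseqid": fields[1],
                    "pident": float(fields[2]),
                    "length": int(fields[3]),
                    "mismatch": int(fields[4]),
                    "gapopen": int(fields[5]),
                    "qstart": int(fields[6]),
                    "qend": int(fields[7]),
                    "sstart": int(fields[8]),
                    "send": int(fields[9]),
                    "evalue": float(fields[10]),
                    "bitscore": float(fields[11]),
                }
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= row["pident"] <= 100.0:
                raise ParseError(
                    f"{path}:{lineno}: percent identity {row['pident']} "
                    "outside [0, 100]"
                )
            if row["evalue"] < 0:
                raise ParseError(f"{path}:{lineno}: negative E-value")
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    if df.empty:
        df = pd.DataFrame(columns=list(HIT_COLUMNS))
    df["genome_id"] = df["sseqid"].str.split("|").str[0]
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the 12 canonical columns as a tab-separated file (no header)."""
    buf = _io.StringIO()
    for row in df.itertuples(index=False):
        fields = [
            row.qseqid, row.sseqid, f"{row.pident:.2f}", str(row.length),
            str(row.mismatch), str(row.gapopen), str(row.qstart),
            str(row.qend), str(row.sstart), str(row.send),
            f"{row.evalue:.3e}", f"{row.bitscore:.1f}",
        ]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Ortholog family tables
# ---------------------------------------------------------------------------

FAMILY_COLUMNS = ("family_id", "genome_id", "protein_id", "annotation")


def read_family_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(FAMILY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: family table missing columns {sorted(missing)}"
        )
    return df[list(FAMILY_COLUMNS)]


def write_family_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(FAMILY_COLUMNS))
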