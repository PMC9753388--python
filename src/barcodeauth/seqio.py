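"""Sequence, alignment, group-map and Newick I/O.

Canonical in-memory types for the pipeline: :class:`SequenceRecord` (one named
nucleotide sequence), :class:`Alignment` (equal-length gapped sequences with a
1-based user-facing column coordinate system) and :class:`GroupMap` (sequence
id -> species / genus / role). FASTA parsing is backed by biopython, Newick by
dendropy.

Alphabet: the full IUPAC nucleotide set plus ``-`` for gaps. Downstream
analyses treat every symbol outside {A, C, G, T} as missing data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "GroupEntry",
    "GroupMap",
    "ParseError",
    "DuplicateIdError",
    "AlphabetError",
    "GroupMapError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_group_map",
    "write_group_map",
    "read_newick",
    "write_newick",
    "encode",
    "decode",
    "ROLES",
    "A",
    "C",
    "G",
    "T",
    "MISSING",
    "GAP_CODE",
]

IUPAC_NUCLEOTIDES = set("ACGTRYSWKMBDHVN-")
ROLES = ("reference", "adulterant", "unknown")

# integer codes used throughout: A,C,G,T then "missing" (any ambiguity code),
# then the gap symbol. Codes < 4 are the only ones that count as observed bases.
A, C, G, T, MISSING, GAP_CODE = 0, 1, 2, 3, 4, 5
GAP = "-"

_ENCODE_TABLE = np.full(256, MISSING, dtype=np.int8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T), (GAP, GAP_CODE)):
    _ENCODE_TABLE[ord(_ch)] = _code
_DECODE_TABLE = np.frombuffer(b"ACGTN-", dtype="S1")


class ParseError(ValueError):
    """Malformed input file."""


class DuplicateIdError(ParseError):
    """Two records in one file share an id."""


class AlphabetError(ParseError):
    """A residue outside the IUPAC nucleotide alphabet."""


class GroupMapError(ValueError):
    """Invalid group-map table."""


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 codes (A=0,C=1,G=2,T=3, missing=4, gap=5)."""
    return _ENCODE_TABLE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; ambiguity detail collapses to ``N``."""
    return _DECODE_TABLE[codes].tobytes().decode("ascii")


@dataclass
class SequenceRecord:
    """One named nucleotide sequence with optional free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence id must be nonempty")
        self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in IUPAC_NUCLEOTIDES:
                raise AlphabetError(
                    f"illegal character {ch!r} in record {self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """Equal-length gapped sequences.

    Columns are 1-based and inclusive in every user-facing report; internal
    arrays are 0-based. No column may consist entirely of gap characters.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ParseError("alignment requires at least one record")
        length = len(records[0].residues)
        if length < 1:
            raise ParseError("alignment length must be >= 1")
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.residues) != length:
                raise ParseError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {length}"
                )
        self.records = records
        self.length = length
        self._matrix = np.vstack([encode(r.residues) for r in records])
        if bool(((self._matrix == GAP_CODE).all(axis=0)).any()):
            raise ParseError("alignment contains an all-gap column")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) int8 code matrix. Do not mutate."""
        return self._matrix

    def row(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; ids deduplicated, residues uppercased, alphabet enforced."""
    path = Path(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython's own syntax failures
        raise ParseError(f"{path}: {exc}") from exc
    if not raw:
        raise ParseError(f"{path}: no FASTA records found")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in raw:
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 70) -> None:
    """Write FASTA wrapped at ``wrap`` columns (readers must accept any wrapping)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[start:start + wrap] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file as an :class:`Alignment`."""
    return Alignment(read_fasta(path))


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    write_fasta(aln.records, path, wrap=wrap)


# ---------------------------------------------------------------------------
# Group map


@dataclass(frozen=True)
class GroupEntry:
    species: str
    genus: str
    role: str


class GroupMap:
    """Maps each sequence id to (species, genus, role).

    Roles: ``reference`` (the authentic species panel), ``adulterant`` (named
    non-target panel members) and ``unknown`` (market queries).
    """

    def __init__(self, entries: dict[str, GroupEntry]):
        if not entries:
            raise GroupMapError("no reference entries: group map is empty")
        for seq_id, entry in entries.items():
            if entry.role not in ROLES:
                raise GroupMapError(
                    f"unknown role {entry.role!r} for {seq_id!r}; allowed roles: {', '.join(ROLES)}"
                )
        if not any(e.role == "reference" for e in entries.values()):
            raise GroupMapError("no reference entries in group map")
        self.entries = dict(entries)

    def __getitem__(self, seq_id: str) -> GroupEntry:
        return self.entries[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def role_of(self, seq_id: str) -> str:
        return self.entries[seq_id].role

    def group_of(self, seq_id: str, level: str = "species") -> str:
        if level not in ("species", "genus"):
            raise GroupMapError(f"level must be 'species' or 'genus', got {level!r}")
        entry = self.entries[seq_id]
        return entry.species if level == "species" else entry.genus

    def members(self, group: str, level: str = "species",
                ids: Sequence[str] | None = None) -> list[str]:
        """Ids (optionally restricted to ``ids``) whose group at ``level`` matches."""
        pool = self.ids if ids is None else list(ids)
        return [i for i in pool if i in self.entries and self.group_of(i, level) == group]

    def reference_species(self) -> str:
        """The single species declared as reference; error if ambiguous."""
        species = sorted({e.species for e in self.entries.values() if e.role == "reference"})
        if len(species) != 1:
            raise GroupMapError(
                f"expected exactly one reference species, found {species!r}"
            )
        return species[0]

    def require_covers(self, ids: Iterable[str]) -> None:
        missing = [i for i in ids if i not in self.entries]
        if missing:
            raise GroupMapError(f"ids missing from group map: {missing!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, e.species, e.genus, e.role) for i, e in self.entries.items()],
            columns=["id", "species", "genus", "role"],
        )


REQUIRED_GROUP_COLUMNS = ("id", "species", "genus", "role")


def read_group_map(path: str | Path) -> GroupMap:
    """Read a delimited (comma or tab, sniffed) table with header id,species,genus,role."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise GroupMapError(f"{path}: cannot parse group map: {exc}") from exc
    missing = [c for c in REQUIRED_GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise GroupMapError(f"{path}: missing column(s) {missing!r}")
    if df.empty:
        raise GroupMapError(f"{path}: no reference entries (table is empty)")
    entries: dict[str, GroupEntry] = {}
    for _, row in df.iterrows():
        seq_id = str(row["id"]).strip()
        if seq_id in entries:
            raise GroupMapError(f"{path}: duplicate id {seq_id!r}")
        entries[seq_id] = GroupEntry(
            species=str(row["species"]).strip(),
            genus=str(row["genus"]).strip(),
            role=str(row["role"]).strip(),
        )
    return GroupMap(entries)


def write_group_map(gm: GroupMap, path: str | Path) -> None:
    gm.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick: branch lengths to 6 decimals, integer bootstrap labels, ``;``-terminated."""
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    Path(path).write_text(newick_string(tree), encoding="utf-8")


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(Path(path)), schema="newick", preserve_underscores=True
    )
    return tree
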