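"""Corpus input/output: proteome FASTA files, taxonomy tables, annotation files
and pathogenicity score tables.

Proteomes are UniProt-style reference proteomes: one FASTA file per proteome,
headers either ``>db|ACCESSION|NAME ...`` (the accession becomes the protein id)
or a plain first-token id. All sequences are uppercased on ingest; a trailing
stop (``*``) is stripped, an internal stop is an error.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

RANKS = ("superkingdom", "kingdom", "phylum")

__all__ = [
    "RANKS",
    "Proteome",
    "TaxonomyTable",
    "PathogenicityRow",
    "CorpusError",
    "read_fasta_proteome",
    "write_fasta_proteome",
    "read_taxonomy",
    "write_taxonomy",
    "read_scores",
    "read_gaf",
    "write_tsv",
]


class CorpusError(ValueError):
    """Malformed or inconsistent corpus input."""


@dataclass(frozen=True)
class Proteome:
    """A reference proteome: a set of protein sequences under one proteome id."""

    proteome_id: str
    proteins: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.proteome_id:
            raise CorpusError("proteome_id must be non-empty")
        for pid, seq in self.proteins.items():
            if not seq:
                raise CorpusError(f"empty sequence for protein {pid!r}")


@dataclass
class TaxonomyTable:
    """proteome_id -> rank labels; empty string means unassigned at that rank."""

    rows: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, proteome_id: str, superkingdom: str = "", kingdom: str = "",
            phylum: str = "") -> None:
        if proteome_id in self.rows:
            raise CorpusError(f"duplicate proteome_id {proteome_id!r}")
        self.rows[proteome_id] = {
            "superkingdom": superkingdom.strip(),
            "kingdom": kingdom.strip(),
            "phylum": phylum.strip(),
        }

    def label(self, proteome_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise CorpusError(f"unknown rank {rank!r}; expected one of {RANKS}")
        try:
            return self.rows[proteome_id][rank]
        except KeyError:
            raise CorpusError(f"proteome {proteome_id!r} missing from taxonomy") from None

    def proteomes(self) -> list[str]:
        return list(self.rows)

    def taxon_size(self, rank: str, taxon: str) -> int:
        """Number of proteomes carrying ``taxon`` at ``rank``."""
        return sum(1 for labels in self.rows.values() if labels[rank] == taxon)

    def __contains__(self, proteome_id: str) -> bool:
        return proteome_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PathogenicityRow:
    """One missense-variant pathogenicity prediction (score in [0, 1])."""

    protein_id: str
    position: int  # 1-based residue index
    alt_residue: str
    score: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CorpusError(f"position must be >= 1, got {self.position}")
        if not (0.0 <= self.score <= 1.0):
            raise CorpusError(f"score {self.score} outside [0, 1]")


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _protein_id_from_header(header: str) -> str:
    # UniProt dialect db|ACC|NAME -> ACC; otherwise first whitespace token.
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def _clean_sequence(raw: str, protein_id: str) -> str:
    seq = raw.upper().rstrip("*")
    if "*" in seq:
        raise CorpusError(f"internal stop codon '*' in protein {protein_id!r}")
    return seq


def read_fasta_proteome(path: str | Path, proteome_id: str) -> Proteome:
    """Read one proteome FASTA file.

    Protein ids come from the second pipe-field of UniProt headers, else the
    first whitespace token. Sequences are uppercased; trailing ``*`` stripped.
    """
    proteins: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            pid = _protein_id_from_header(record.description or record.id)
            if pid in proteins:
                raise CorpusError(
                    f"duplicate protein_id {pid!r} in proteome {proteome_id!r}")
            proteins[pid] = _clean_sequence(str(record.seq), pid)
    if not proteins:
        raise CorpusError(f"no FASTA records in {path}")
    return Proteome(proteome_id=proteome_id, proteins=proteins)


def write_fasta_proteome(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for pid in proteome.proteins:
            out.write(f">{pid}\n")
            seq = proteome.proteins[pid]
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


_TAXONOMY_COLUMNS = ("proteome_id", "superkingdom", "kingdom", "phylum")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read the taxonomy TSV (header: proteome_id superkingdom kingdom phylum)."""
    table = TaxonomyTable()
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _TAXONOMY_COLUMNS:
            raise CorpusError(
                f"taxonomy header {header} != expected {list(_TAXONOMY_COLUMNS)}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 4:
                raise CorpusError(f"taxonomy line {lineno}: expected 4 columns")
            table.add(*cells)
    return table


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(_TAXONOMY_COLUMNS) + "\n")
        for pid, labels in table.rows.items():
            out.write("\t".join(
                [pid, labels["superkingdom"], labels["kingdom"], labels["phylum"]]) + "\n")


def read_scores(path: str | Path) -> list[PathogenicityRow]:
    """Read a per-residue pathogenicity score TSV (protein_id, position, alt, score)."""
    rows: list[PathogenicityRow] = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "position", "alt", "score"]:
            raise CorpusError(f"score table header {header} not recognised")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            try:
                position = int(cells[1])
                score = float(cells[3])
            except (ValueError, IndexError) as exc:
                raise CorpusError(f"score table line {lineno}: {exc}") from exc
            rows.append(PathogenicityRow(cells[0], position, cells[2], score))
    return rows


def write_scores(rows: Iterable[PathogenicityRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("protein_id\tposition\talt\tscore\n")
        for r in rows:
            out.write(f"{r.protein_id}\t{r.position}\t{r.alt_residue}\t{r.score:.6g}\n")


def read_gaf(path: str | Path, aspect: str | None = None) -> dict[str, set[str]]:
    """Read a GAF 2.2 annotation file into protein id -> set of GO term ids.

    ``aspect`` optionally restricts to one namespace code (P, F or C, GAF
    column 9). Comment lines (``!``) are skipped; NOT-qualified annotations
    are ignored.
    """
    annotations: dict[str, set[str]] = {}
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise CorpusError(f"GAF line with {len(cols)} columns (need >= 9)")
            if "NOT" in cols[3].split("|"):
                continue
            if aspect is not None and cols[8] != aspect:
                continue
            annotations.setdefault(cols[1], set()).add(cols[4])
    return annotations


def write_tsv(path: str | Path, header: list[str], rows: Iterable[list]) -> None:
    """Write a plain TSV (header row, UTF-8, no quoting)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(header) + "\n")
        for row in rows:
            out.write("\t".join(str(c) for c in row) + "\n")
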