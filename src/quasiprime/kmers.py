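"""Peptide k-mer extraction and the proteome presence index.

A presence index maps each k-mer to the set of proteomes that contain it at
least once (presence, not multiplicity). The index is sharded by k-mer prefix
so a large corpus can be aggregated and written shard by shard; shards
partition the k-mer space and are traversed in lexicographic order, making
the output byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator

from .io import Proteome

#: The 20 canonical amino acids, lexicographic.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

__all__ = ["CANONICAL_AA", "KmerPresence", "ShardPlan", "extract_kmers",
           "build_presence_index", "write_shards", "read_shards"]


@dataclass(frozen=True)
class KmerPresence:
    """A k-mer and the set of proteome ids containing it."""

    kmer: str
    proteomes: frozenset[str]


@dataclass(frozen=True)
class ShardPlan:
    """Partition of k-mer space by residue prefix of fixed length.

    prefix_length=2 yields 400 shards; every canonical k-mer belongs to
    exactly one shard.
    """

    prefix_length: int = 2

    def __post_init__(self) -> None:
        if self.prefix_length < 1:
            raise ValueError("prefix_length must be >= 1")

    def shard_ids(self) -> list[str]:
        return ["".join(p) for p in product(CANONICAL_AA, repeat=self.prefix_length)]

    def shard_of(self, kmer: str) -> str:
        return kmer[: self.prefix_length]


def extract_kmers(sequence: str, k: int) -> set[str]:
    """Every length-k window of ``sequence`` made solely of canonical residues.

    Windows containing ambiguity codes (X B Z J), stops (*) or the
    non-standard residues U/O are skipped; the result is deduplicated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    if k > n:
        return set()
    out: set[str] = set()
    # Track the next position at or after which a non-canonical residue sits,
    # so runs of clean sequence are windowed without per-residue re-checks.
    bad = -1  # index of the most recent non-canonical residue seen
    for i, ch in enumerate(sequence):
        if ch not in _CANONICAL_SET:
            bad = i
        elif i - bad >= k:
            out.add(sequence[i - k + 1: i + 1])
    return out


def build_presence_index(
    corpus: Iterable[Proteome],
    k: int,
    plan: ShardPlan | None = None,
) -> Iterator[KmerPresence]:
    """Stream KmerPresence records for a corpus, sorted lexicographically.

    Each (k-mer, proteome) incidence appears exactly once regardless of how
    many proteins or positions within the proteome contain the k-mer.
    """
    plan = plan or ShardPlan()
    shards: dict[str, dict[str, set[str]]] = {}
    n_proteomes = 0
    for proteome in corpus:
        n_proteomes += 1
        seen: set[str] = set()
        for seq in proteome.proteins.values():
            seen |= extract_kmers(seq, k)
        for kmer in seen:
            shards.setdefault(plan.shard_of(kmer), {}).setdefault(
                kmer, set()).add(proteome.proteome_id)
    if n_proteomes == 0:
        raise ValueError("corpus is empty")
    for shard_id in sorted(shards):
        shard = shards[shard_id]
        for kmer in sorted(shard):
            yield KmerPresence(kmer=kmer, proteomes=frozenset(shard[kmer]))


def write_shards(
    presence: Iterable[KmerPresence],
    out_dir: str | Path,
    plan: ShardPlan | None = None,
) -> list[Path]:
    """Write the presence stream to per-shard TSVs (kmer TAB sorted ids)."""
    plan = plan or ShardPlan()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    handle = None
    current = None
    try:
        for rec in presence:
            shard_id = plan.shard_of(rec.kmer)
            if shard_id != current:
                if handle is not None:
                    handle.close()
                path = out_dir / f"shard_{shard_id}.tsv"
                try:
                    handle = open(path, "w", encoding="utf-8")
                except OSError as exc:
                    raise OSError(f"cannot write shard {shard_id}: {exc}") from exc
                paths.append(path)
                current = shard_id
            handle.write(f"{rec.kmer}\t{','.join(sorted(rec.proteomes))}\n")
    finally:
        if handle is not None:
            handle.close()
    return paths


def read_shards(index_dir: str | Path) -> Iterator[KmerPresence]:
    """Read back shard TSVs in lexicographic shard order."""
    for path in sorted(Path(index_dir).glob("shard_*.tsv")):
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                kmer, ids = line.rstrip("\n").split("\t")
                yield KmerPresence(kmer=kmer, proteomes=frozenset(ids.split(",")))
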