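"""Calling taxonomic quasi-primes and their ε-score summary statistics.

A taxonomic quasi-prime is a peptide k-mer present in at least one proteome of
a taxon (at a given rank) and absent from every proteome outside that taxon.
The ε-score measures how widespread the k-mer is within its taxon: the
percentage of the taxon's proteomes that contain it. ε = 0 means complete
absence; ε = 100 means universal presence.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import RANKS, TaxonomyTable
from .kmers import KmerPresence

__all__ = ["QuasiPrimeRecord", "TaxonSummary", "epsilon_score",
           "call_quasiprimes", "summarize"]


@dataclass(frozen=True)
class QuasiPrimeRecord:
    """A taxon-exclusive k-mer at one rank, with its ε-score."""

    kmer: str
    rank: str
    taxon: str
    n_present: int
    n_taxon: int
    epsilon: float


@dataclass(frozen=True)
class TaxonSummary:
    """Per-taxon quasi-prime count with median (ε_M) and maximum (ε_max) ε-score."""

    rank: str
    taxon: str
    n_quasiprimes: int
    epsilon_median: float
    epsilon_max: float


def epsilon_score(n_present: int, n_taxon: int) -> float:
    """Percentage of a taxon's proteomes containing a k-mer: 100·n_present/n_taxon."""
    if n_taxon < 1:
        raise ValueError("n_taxon must be >= 1 (taxon with no proteomes is undefined)")
    if not 0 <= n_present <= n_taxon:
        raise ValueError(f"n_present {n_present} outside [0, {n_taxon}]")
    return 100.0 * n_present / n_taxon


def call_quasiprimes(
    presence: Iterable[KmerPresence],
    taxonomy: TaxonomyTable,
    rank: str,
) -> Iterator[QuasiPrimeRecord]:
    """Emit quasi-prime records at ``rank`` from a presence stream.

    A k-mer is exclusive to taxon T iff every proteome containing it is
    labeled T at this rank. Proteomes unassigned at the rank count as outside
    every taxon, so their presence vetoes exclusivity; they are also excluded
    from every denominator.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    taxon_sizes: dict[str, int] = {}
    for rec in presence:
        missing = [p for p in rec.proteomes if p not in taxonomy]
        if missing:
            raise ValueError(f"proteomes missing from taxonomy: {sorted(missing)}")
        labels = {taxonomy.label(p, rank) for p in rec.proteomes}
        if len(labels) != 1:
            continue
        taxon = labels.pop()
        if not taxon:  # all carriers unassigned at this rank
            continue
        if taxon not in taxon_sizes:
            taxon_sizes[taxon] = taxonomy.taxon_size(rank, taxon)
        n_taxon = taxon_sizes[taxon]
        n_present = len(rec.proteomes)
        yield QuasiPrimeRecord(
            kmer=rec.kmer,
            rank=rank,
            taxon=taxon,
            n_present=n_present,
            n_taxon=n_taxon,
            epsilon=epsilon_score(n_present, n_taxon),
        )


def summarize(records: Iterable[QuasiPrimeRecord]) -> list[TaxonSummary]:
    """Per (rank, taxon): quasi-prime count, median ε (ε_M) and max ε (ε_max).

    The median of an even-sized list is the mean of the central pair.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        groups.setdefault((rec.rank, rec.taxon), []).append(rec.epsilon)
    out = []
    for (rank, taxon) in sorted(groups):
        eps = groups[(rank, taxon)]
        out.append(TaxonSummary(
            rank=rank,
            taxon=taxon,
            n_quasiprimes=len(eps),
            epsilon_median=statistics.median(eps),
            epsilon_max=max(eps),
        ))
    return out
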