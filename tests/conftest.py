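"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import random

import pytest

from quasiprime.io import Proteome, TaxonomyTable
from quasiprime.kmers import CANONICAL_AA


def brute_force_presence(corpus: list[Proteome], k: int) -> dict[str, set[str]]:
    """In-memory k-mer -> proteome-set map by direct window scanning."""
    canonical = set(CANONICAL_AA)
    index: dict[str, set[str]] = {}
    for proteome in corpus:
        for seq in proteome.proteins.values():
            for i in range(len(seq) - k + 1):
                window = seq[i:i + k]
                if set(window) <= canonical:
                    index.setdefault(window, set()).add(proteome.proteome_id)
    return index


def brute_force_quasiprimes(
    corpus: list[Proteome], taxonomy: TaxonomyTable, k: int, rank: str,
) -> dict[str, tuple[str, int]]:
    """Direct scan for taxon-exclusive k-mers: kmer -> (taxon, n_present).

    A k-mer qualifies iff every proteome containing it carries the same
    non-empty label at the rank.
    """
    out: dict[str, tuple[str, int]] = {}
    for kmer, proteomes in brute_force_presence(corpus, k).items():
        labels = {taxonomy.label(p, rank) for p in proteomes}
        if len(labels) == 1 and (taxon := labels.pop()):
            out[kmer] = (taxon, len(proteomes))
    return out


def random_corpus(
    rng: random.Random,
    n_proteomes: int = 6,
    n_phyla: int = 3,
    proteins_per_proteome: int = 3,
    max_len: int = 60,
    alphabet: str = CANONICAL_AA + "X",
) -> tuple[list[Proteome], TaxonomyTable]:
    """Small random corpus (optionally with ambiguity codes) plus taxonomy."""
    taxonomy = TaxonomyTable()
    corpus = []
    for i in range(n_proteomes):
        pid = f"p{i + 1}"
        phylum = f"Phylum{rng.randrange(n_phyla) + 1}"
        taxonomy.add(pid, "SK1", "K1", phylum)
        proteins = {
            f"{pid}_prot{j}": "".join(
                rng.choice(alphabet) for _ in range(rng.randint(10, max_len)))
            for j in range(proteins_per_proteome)
        }
        corpus.append(Proteome(proteome_id=pid, proteins=proteins))
    return corpus, taxonomy


@pytest.fixture
def toy_corpus() -> tuple[list[Proteome], TaxonomyTable]:
    """Five proteomes in two phyla with a hand-placed Chordata-exclusive k-mer."""
    taxonomy = TaxonomyTable()
    for pid, phylum in [("p1", "A"), ("p2", "A"), ("p3", "A"),
                        ("p4", "B"), ("p5", "B")]:
        taxonomy.add(pid, "Euk", "Meta", phylum)
    corpus = [
        Proteome("p1", {"p1_x": "MWDCMEVAAAA", "p1_y": "ACDEFGHIK"}),
        Proteome("p2", {"p2_x": "GGGMWDCMEV"}),
        Proteome("p3", {"p3_x": "ACDEFGHIKLMN"}),
        Proteome("p4", {"p4_x": "NNNNNNNNNN"}),
        Proteome("p5", {"p5_x": "QQQQQQQQQQ"}),
    ]
    return corpus, taxonomy
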