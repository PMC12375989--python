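"""BLOSUM62-conservative substitution neighborhoods and consensus patterns.

A single-residue variant of a seed peptide is *biologically conservative* when
the substitution scores strictly greater than zero in BLOSUM62 (half-bit
integer scores). The set of retained variants of a seed collapses into a
consensus bracket pattern listing the allowed residues per position, e.g.
``[LM][FW][DEN]CM[EKQ][ILV]``.

The matrix is embedded as a constant table (the standard BLOSUM62 of Henikoff
& Henikoff, 20 canonical residues) so results do not drift with external data
files; tests cross-check it against Biopython's copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import Proteome, TaxonomyTable
from .kmers import CANONICAL_AA
from .matching import AhoCorasick, render_pattern

__all__ = ["BLOSUM62", "VariantSet", "ConsensusPattern", "conservative_variants",
           "map_variants", "consensus_pattern"]

# Standard BLOSUM62, canonical 20x20 block, row order = CANONICAL_AA
# (A C D E F G H I K L M N P Q R S T V W Y).
_B62_ROWS = """
 4  0 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1 -1  1  0  0 -3 -2
 0  9 -3 -4 -2 -3 -3 -1 -3 -1 -1 -3 -3 -3 -3 -1 -1 -1 -2 -2
-2 -3  6  2 -3 -1 -1 -3 -1 -4 -3  1 -1  0 -2  0 -1 -3 -4 -3
-1 -4  2  5 -3 -2  0 -3  1 -3 -2  0 -1  2  0  0 -1 -2 -3 -2
-2 -2 -3 -3  6 -3 -1  0 -3  0  0 -3 -4 -3 -3 -2 -2 -1  1  3
 0 -3 -1 -2 -3  6 -2 -4 -2 -4 -3  0 -2 -2 -2  0 -2 -3 -2 -3
-2 -3 -1  0 -1 -2  8 -3 -1 -3 -2  1 -2  0  0 -1 -2 -3 -2  2
-1 -1 -3 -3  0 -4 -3  4 -3  2  1 -3 -3 -3 -3 -2 -1  3 -3 -1
-1 -3 -1  1 -3 -2 -1 -3  5 -2 -1  0 -1  1  2  0 -1 -2 -3 -2
-1 -1 -4 -3  0 -4 -3  2 -2  4  2 -3 -3 -2 -2 -2 -1  1 -2 -1
-1 -1 -3 -2  0 -3 -2  1 -1  2  5 -2 -2  0 -1 -1 -1  1 -1 -1
-2 -3  1  0 -3  0  1 -3  0 -3 -2  6 -2  0  0  1  0 -3 -4 -2
-1 -3 -1 -1 -4 -2 -2 -3 -1 -3 -2 -2  7 -1 -2 -1 -1 -2 -4 -3
-1 -3  0  2 -3 -2  0 -3  1 -2  0  0 -1  5  1  0 -1 -2 -2 -1
-1 -3 -2  0 -3 -2  0 -3  2 -2 -1  0 -2  1  5 -1 -1 -3 -3 -2
 1 -1  0  0 -2  0 -1 -2  0 -2 -1  1 -1  0 -1  4  1 -2 -3 -2
 0 -1 -1 -1 -2 -2 -2 -1 -1 -1 -1  0 -1 -1 -1  1  5  0 -2 -2
 0 -1 -3 -2 -1 -3 -3  3 -2  1  1 -3 -2 -2 -3 -2  0  4 -3 -1
-3 -2 -4 -3  1 -2 -2 -3 -3 -2 -1 -4 -4 -2 -3 -3 -2 -3 11  2
-2 -2 -3 -2  3 -3  2 -1 -2 -1 -1 -2 -3 -1 -2 -2 -2 -1  2  7
"""

#: BLOSUM62 substitution scores: BLOSUM62[a][b] -> int, canonical residues only.
BLOSUM62: dict[str, dict[str, int]] = {
    a: {b: int(v) for b, v in zip(CANONICAL_AA, row.split())}
    for a, row in zip(CANONICAL_AA, _B62_ROWS.strip().splitlines())
}

_CANONICAL = frozenset(CANONICAL_AA)


def _check_canonical(peptide: str) -> None:
    bad = sorted(set(peptide) - _CANONICAL)
    if bad:
        raise ValueError(
            f"non-canonical residues {bad} in peptide {peptide!r} "
            "(ambiguity codes X/B/Z/J, stops and U/O are not allowed)")


@dataclass(frozen=True)
class VariantSet:
    """A seed peptide and its conservative single-substitution variants.

    ``substitutions`` records, per variant, the (position, alt) pair in
    (0-based position, residue) order; ``variants`` is the same information as
    full peptide strings.
    """

    seed: str
    substitutions: tuple[tuple[int, str], ...]

    @property
    def variants(self) -> list[str]:
        return [self.seed[:i] + alt + self.seed[i + 1:]
                for i, alt in self.substitutions]

    def __len__(self) -> int:
        return len(self.substitutions)


def conservative_variants(
    seed: str,
    matrix: Mapping[str, Mapping[str, int]] = BLOSUM62,
) -> VariantSet:
    """All Hamming-1 neighbors of ``seed`` with strictly positive substitution score.

    Only canonical target residues are considered; ordering is deterministic by
    (position, residue).
    """
    if not seed:
        raise ValueError("seed peptide must be non-empty")
    _check_canonical(seed)
    subs = []
    for i, ref in enumerate(seed):
        row = matrix[ref]
        for alt in CANONICAL_AA:
            if alt != ref and row[alt] > 0:
                subs.append((i, alt))
    return VariantSet(seed=seed, substitutions=tuple(subs))


def map_variants(
    vset: VariantSet,
    corpus: Iterable[Proteome],
    taxonomy: TaxonomyTable,
    rank: str,
    seed_taxon: str | None = None,
) -> dict[str, str]:
    """Classify each variant as absent / inside-only / outside at ``rank``.

    ``inside-only`` means the variant occurs only in proteomes of the seed's
    taxon; ``outside`` means it occurs in at least one proteome outside. The
    seed taxon is given explicitly or inferred from the proteomes containing
    the seed itself.
    """
    corpus = list(corpus)
    variants = vset.variants
    automaton = AhoCorasick([vset.seed] + variants)
    found_in: dict[str, set[str]] = {p: set() for p in [vset.seed] + variants}
    for proteome in corpus:
        for seq in proteome.proteins.values():
            for pat, _ in automaton.finditer(seq):
                found_in[pat].add(proteome.proteome_id)
    if seed_taxon is None:
        labels = {taxonomy.label(p, rank) for p in found_in[vset.seed]}
        labels.discard("")
        if len(labels) != 1:
            raise ValueError(
                f"cannot infer seed taxon: seed maps to taxa {sorted(labels)}")
        seed_taxon = labels.pop()
    status: dict[str, str] = {}
    for variant in variants:
        carriers = found_in[variant]
        if not carriers:
            status[variant] = "absent"
        elif all(taxonomy.label(p, rank) == seed_taxon for p in carriers):
            status[variant] = "inside-only"
        else:
            status[variant] = "outside"
    return status


@dataclass(frozen=True)
class ConsensusPattern:
    """Per-position residue sets over a seed and its retained variants."""

    seed: str
    position_sets: tuple[frozenset[str], ...]

    def render(self) -> str:
        return render_pattern(self.position_sets)


def consensus_pattern(seed: str, retained: Iterable[str]) -> ConsensusPattern:
    """Collapse a seed and its retained Hamming-1 variants into a bracket pattern.

    Every position set contains the seed residue plus any variant residues at
    that position; single-residue positions render bare, multi-residue ones as
    alphabetically sorted brackets.
    """
    _check_canonical(seed)
    sets: list[set[str]] = [{r} for r in seed]
    for variant in retained:
        if len(variant) != len(seed):
            raise ValueError(f"variant {variant!r} length differs from seed")
        diffs = [i for i, (a, b) in enumerate(zip(seed, variant)) if a != b]
        if len(diffs) != 1:
            raise ValueError(
                f"variant {variant!r} is not a single-substitution neighbor of {seed!r}")
        sets[diffs[0]].add(variant[diffs[0]])
    return ConsensusPattern(
        seed=seed, position_sets=tuple(frozenset(s) for s in sets))
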