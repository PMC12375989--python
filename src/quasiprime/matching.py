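"""Multi-pattern peptide matching and trie-based taxonomic classification.

Exact peptides are matched with an Aho–Corasick automaton (all patterns in one
pass per protein, overlapping occurrences included). Consensus patterns in
bracket syntax (e.g. ``[LM][FW][DEN]CM[EKQ][ILV]``) are held per taxon in a
prefix-tree structure whose edges carry residue alternatives; scanning a novel
proteome against per-taxon tries yields a hit profile and an ε-weighted
likelihood assignment to the most probable lineage.

Coordinates are 1-based and inclusive throughout: a seven-mer starting at
residue 111 spans 111–117.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping, Sequence

import math

from .io import Proteome

__all__ = ["PeptideHit", "PatternTrie", "TaxonProfile", "AhoCorasick",
           "match_peptides", "parse_pattern", "render_pattern",
           "build_tries", "classify_proteome"]


@dataclass(frozen=True)
class PeptideHit:
    """One occurrence of a peptide in a protein (1-based inclusive coordinates)."""

    peptide: str
    proteome_id: str
    protein_id: str
    start: int
    end: int


class AhoCorasick:
    """Aho–Corasick automaton over amino-acid strings.

    Reports every occurrence of every pattern, overlaps included, in a single
    pass over each text.
    """

    def __init__(self, patterns: Iterable[str]):
        patterns = list(dict.fromkeys(patterns))
        if not patterns:
            raise ValueError("no patterns")
        for p in patterns:
            if not p:
                raise ValueError("empty peptide pattern")
        # goto is a list of dicts: state -> {char: state}
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        self._fail: list[int] = [0]
        for pat in patterns:
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(pat)
        # BFS to build failure links and merge outputs
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def finditer(self, text: str) -> Iterator[tuple[str, int]]:
        """Yield (pattern, 0-based end index) for every occurrence in text."""
        state = 0
        goto, fail, out = self._goto, self._fail, self._out
        for i, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for pat in out[state]:
                yield pat, i


def match_peptides(
    peptides: Iterable[str],
    corpus: Iterable[Proteome],
) -> list[PeptideHit]:
    """Locate every occurrence of every peptide across a corpus.

    Overlapping occurrences are all reported; coordinates are 1-based
    inclusive.
    """
    automaton = AhoCorasick(peptides)
    hits: list[PeptideHit] = []
    for proteome in corpus:
        for protein_id, seq in proteome.proteins.items():
            for pat, end0 in automaton.finditer(seq):
                start = end0 - len(pat) + 2  # 1-based start
                hits.append(PeptideHit(
                    peptide=pat,
                    proteome_id=proteome.proteome_id,
                    protein_id=protein_id,
                    start=start,
                    end=end0 + 1,
                ))
    return hits


# ---------------------------------------------------------------------------
# Bracket patterns and per-taxon tries


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Decompose bracket syntax into per-position residue sets.

    ``C[AB]T`` -> [{C}, {A, B}, {T}]. Raises on unbalanced brackets or empty
    groups, reporting the character position.
    """
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed '[' at position {i} in {pattern!r}")
            group = pattern[i + 1: j]
            if not group:
                raise ValueError(f"empty bracket group at position {i} in {pattern!r}")
            sets.append(frozenset(group))
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unmatched ']' at position {i} in {pattern!r}")
        else:
            sets.append(frozenset(ch))
            i += 1
    if not sets:
        raise ValueError("empty pattern")
    return sets


def render_pattern(sets: Sequence[Iterable[str]]) -> str:
    """Render per-position residue sets back to bracket syntax.

    Single-residue positions are bare letters; multi-residue positions are
    alphabetically sorted inside brackets.
    """
    out = []
    for s in sets:
        residues = sorted(s)
        out.append(residues[0] if len(residues) == 1 else "[" + "".join(residues) + "]")
    return "".join(out)


@dataclass
class PatternTrie:
    """Per-taxon prefix tree of fixed-length patterns with per-leaf ε-scores.

    Each pattern is stored as its per-position residue sets; the trie accepts
    exactly the expansion set (the Cartesian product of position alternatives).
    """

    taxon: str
    patterns: list[tuple[str, list[frozenset[str]], float]] = field(default_factory=list)

    def add(self, pattern: str, epsilon: float) -> None:
        if not 0 < epsilon <= 100:
            raise ValueError(f"epsilon {epsilon} outside (0, 100]")
        self.patterns.append((pattern, parse_pattern(pattern), epsilon))

    def expansion_size(self, pattern_index: int) -> int:
        return math.prod(len(s) for s in self.patterns[pattern_index][1])

    def expand(self, pattern_index: int) -> set[str]:
        sets = self.patterns[pattern_index][1]
        return {"".join(p) for p in product(*(sorted(s) for s in sets))}

    def accepts(self, peptide: str) -> bool:
        """True iff some stored pattern's expansion contains ``peptide``."""
        return any(
            len(sets) == len(peptide) and all(c in s for c, s in zip(peptide, sets))
            for _, sets, _ in self.patterns
        )

    def _scan_protein(self, seq: str, sets: list[frozenset[str]]) -> bool:
        k = len(sets)
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in sets[j] for j in range(k)):
                return True
        return False

    def matched_patterns(self, proteome: Proteome) -> list[tuple[str, float]]:
        """Patterns of this trie with at least one occurrence in the proteome."""
        matched = []
        for pattern, sets, eps in self.patterns:
            if any(self._scan_protein(seq, sets) for seq in proteome.proteins.values()):
                matched.append((pattern, eps))
        return matched


@dataclass(frozen=True)
class TaxonProfile:
    """Per-taxon hit counts and normalized likelihood scores for one proteome."""

    hit_counts: Mapping[str, int]
    scores: Mapping[str, float]
    assigned_taxon: str


def build_tries(peptide_sets: Mapping[str, list[tuple[str, float]]]) -> list[PatternTrie]:
    """One PatternTrie per taxon from {taxon: [(pattern-or-peptide, ε), ...]}."""
    tries = []
    for taxon in sorted(peptide_sets):
        trie = PatternTrie(taxon=taxon)
        for pattern, eps in peptide_sets[taxon]:
            trie.add(pattern, eps)
        tries.append(trie)
    return tries


def classify_proteome(
    proteome: Proteome,
    tries: list[PatternTrie],
    min_hits: int = 1,
) -> TaxonProfile:
    """Assign a proteome to the taxon whose patterns it matches best.

    score(T) = Σ over matched patterns of log1p(ε/100), divided by the number
    of patterns in T's trie; the assignment is the argmax (ties broken by
    lexicographically smallest taxon). Below ``min_hits`` total matches the
    assignment is "unclassified".
    """
    if not tries:
        raise ValueError("need at least one pattern trie")
    if not proteome.proteins:
        raise ValueError("proteome has no proteins")
    hit_counts: dict[str, int] = {}
    scores: dict[str, float] = {}
    for trie in tries:
        matched = trie.matched_patterns(proteome)
        hit_counts[trie.taxon] = len(matched)
        scores[trie.taxon] = (
            sum(math.log1p(eps / 100.0) for _, eps in matched) / len(trie.patterns)
            if trie.patterns else 0.0
        )
    if sum(hit_counts.values()) < min_hits:
        assigned = "unclassified"
    else:
        assigned = min(scores, key=lambda t: (-scores[t], t))
    return TaxonProfile(hit_counts=hit_counts, scores=scores, assigned_taxon=assigned)
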