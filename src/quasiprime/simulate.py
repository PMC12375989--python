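"""Synthetic corpora, annotations and pathogenicity scores with exact ground truth.

The generator emulates the statistical structure the analysis modules assume:

* multi-taxon proteome corpora of uniform-random canonical residues with
  planted taxon-exclusive peptides at a controlled presence fraction (so the
  expected ε-score is known exactly);
* per-species annotation tables with terms planted at a target odds ratio;
* two-population pathogenicity score mixtures with controlled pathogenic
  (score > 0.9) mass inside vs. outside quasi-prime loci.

Corpus text is produced by ``random.Random`` (integer state only), so a given
seed yields byte-identical output on every platform. After planting, the
corpus is re-scanned and any chance background occurrence of a planted peptide
outside its assigned proteome set is rewritten, making the manifest exact
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random
from .io import PathogenicityRow, Proteome, TaxonomyTable
from .kmers import CANONICAL_AA
from .matching import PeptideHit

__all__ = ["TaxonSpec", "PlantSpec", "EnrichmentPlantSpec", "PathoMixtureSpec",
           "FixtureConfig", "generate_corpus", "generate_annotations",
           "generate_scores", "CorpusManifest"]


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon's labels at each rank and its proteome count."""

    superkingdom: str
    kingdom: str
    phylum: str
    n_proteomes: int

    def label(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass(frozen=True)
class PlantSpec:
    """A peptide to plant exclusively within one taxon.

    ``peptide`` may be "random" to draw a fresh random k-mer. The peptide is
    inserted into ceil(presence_fraction × n) proteomes of the taxon, so the
    expected ε-score is 100 × ceil(f·n)/n.
    """

    rank: str
    taxon: str
    peptide: str = "random"
    presence_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentPlantSpec:
    term: str
    odds_ratio: float
    n_species: int

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class PathoMixtureSpec:
    """Pathogenic-score mixture: pathogenic mass per arm, benign mass mirrored."""

    inside_pathogenic_fraction: float
    outside_pathogenic_fraction: float
    n_inside: int
    n_outside: int

    def __post_init__(self) -> None:
        for f in (self.inside_pathogenic_fraction, self.outside_pathogenic_fraction):
            if not 0 <= f <= 1:
                raise ValueError("pathogenic fractions must lie in [0, 1]")


@dataclass
class FixtureConfig:
    seed: int = 0
    taxa: list[TaxonSpec] = field(default_factory=lambda: [
        TaxonSpec("Eukaryota", "Metazoa", "Chordata", 8),
        TaxonSpec("Eukaryota", "Metazoa", "Arthropoda", 8),
    ])
    proteins_per_proteome: int = 20
    protein_length: int = 120
    k: int = 7
    planted_quasiprimes: list[PlantSpec] = field(default_factory=list)
    planted_enrichment: list[EnrichmentPlantSpec] = field(default_factory=list)
    patho_mixture: PathoMixtureSpec | None = None


@dataclass(frozen=True)
class PlantedMarker:
    rank: str
    taxon: str
    peptide: str
    proteome_ids: frozenset[str]
    n_taxon: int

    @property
    def expected_epsilon(self) -> float:
        return 100.0 * len(self.proteome_ids) / self.n_taxon


@dataclass
class CorpusManifest:
    """Exact ground truth for a generated corpus."""

    planted: list[PlantedMarker] = field(default_factory=list)


def _random_peptide(rng: Random, k: int) -> str:
    return "".join(rng.choice(CANONICAL_AA) for _ in range(k))


def generate_corpus(
    cfg: FixtureConfig,
) -> tuple[list[Proteome], TaxonomyTable, CorpusManifest]:
    """Generate a seeded corpus with exactly-known planted taxon-exclusive peptides."""
    rng = Random(cfg.seed)
    if any(len(p.peptide) != cfg.k for p in cfg.planted_quasiprimes
           if p.peptide != "random"):
        raise ValueError("planted peptide length must equal k")
    if cfg.k > cfg.protein_length:
        raise ValueError("planted peptide longer than protein")

    taxonomy = TaxonomyTable()
    sequences: dict[str, dict[str, list[str]]] = {}
    taxon_members: dict[tuple[str, str], list[str]] = {}
    for spec in cfg.taxa:
        for i in range(spec.n_proteomes):
            pid = f"{spec.phylum}_{i + 1:03d}"
            taxonomy.add(pid, spec.superkingdom, spec.kingdom, spec.phylum)
            sequences[pid] = {
                f"{pid}_prot{j + 1:03d}":
                    [rng.choice(CANONICAL_AA) for _ in range(cfg.protein_length)]
                for j in range(cfg.proteins_per_proteome)
            }
            for rank in ("superkingdom", "kingdom", "phylum"):
                taxon_members.setdefault((rank, spec.label(rank)), [])
        for rank in ("superkingdom", "kingdom", "phylum"):
            taxon_members[(rank, spec.label(rank))].extend(
                f"{spec.phylum}_{i + 1:03d}" for i in range(spec.n_proteomes))

    # plant peptides
    manifest = CorpusManifest()
    planted_peptides: set[str] = set()
    insertions: dict[str, list[tuple[str, str, int]]] = {}
    for plant in cfg.planted_quasiprimes:
        members = taxon_members.get((plant.rank, plant.taxon))
        if not members:
            raise ValueError(f"no proteomes for taxon {plant.taxon!r} at {plant.rank}")
        peptide = plant.peptide
        while peptide == "random" or peptide in planted_peptides:
            peptide = _random_peptide(rng, cfg.k)
        planted_peptides.add(peptide)
        n_carriers = math.ceil(plant.presence_fraction * len(members))
        carriers = rng.sample(members, n_carriers)
        for pid in carriers:
            protein_id = rng.choice(sorted(sequences[pid]))
            pos = rng.randrange(0, cfg.protein_length - cfg.k + 1)
            sequences[pid][protein_id][pos:pos + cfg.k] = list(peptide)
            insertions.setdefault(peptide, []).append((pid, protein_id, pos))
        manifest.planted.append(PlantedMarker(
            rank=plant.rank, taxon=plant.taxon, peptide=peptide,
            proteome_ids=frozenset(carriers), n_taxon=len(members)))

    _repair_collisions(sequences, manifest, insertions, rng, cfg.k)

    corpus = [
        Proteome(proteome_id=pid,
                 proteins={prot: "".join(chars) for prot, chars in prots.items()})
        for pid, prots in sequences.items()
    ]
    return corpus, taxonomy, manifest


def _repair_collisions(
    sequences: dict[str, dict[str, list[str]]],
    manifest: CorpusManifest,
    insertions: dict[str, list[tuple[str, str, int]]],
    rng: Random,
    k: int,
) -> None:
    """Rewrite chance background occurrences of planted peptides.

    An occurrence is allowed only in the proteomes the plant was assigned to;
    anywhere else (other taxa, or unassigned proteomes of the same taxon) the
    window is replaced with fresh random residues. Repeats until clean.
    """
    allowed = {m.peptide: m.proteome_ids for m in manifest.planted}
    protected = {
        (pid, prot, offset)
        for peptide, sites in insertions.items()
        for (pid, prot, pos) in sites
        for offset in range(pos, pos + k)
    }
    for _ in range(100):
        dirty = False
        for pid, prots in sequences.items():
            for prot, chars in prots.items():
                text = "".join(chars)
                for peptide, allowed_pids in allowed.items():
                    if pid in allowed_pids:
                        continue
                    start = text.find(peptide)
                    while start != -1:
                        for off in range(start, start + k):
                            if (pid, prot, off) not in protected:
                                chars[off] = rng.choice(CANONICAL_AA)
                        dirty = True
                        text = "".join(chars)
                        start = text.find(peptide, start + 1)
        if not dirty:
            return
    raise RuntimeError("collision repair did not converge")


def generate_annotations(
    cfg: FixtureConfig,
    study_size: int = 50,
    background_size: int = 500,
    baseline_prob: float = 0.1,
    n_null_terms: int = 0,
) -> tuple[dict[str, tuple[set[str], set[str], dict[str, set[str]]]], dict]:
    """Per-species study/background sets and annotations with planted odds ratios.

    For a planted term with odds ratio OR, study proteins carry the term with
    probability p1 such that odds(p1) = OR × odds(baseline_prob); background-only
    proteins carry it with the baseline probability. Null terms are annotated
    independently of study membership.
    """
    rng = Random(cfg.seed + 1)
    if study_size > background_size:
        raise ValueError("study_size cannot exceed background_size")
    n_species = max([p.n_species for p in cfg.planted_enrichment], default=1)
    species_data: dict[str, tuple[set[str], set[str], dict[str, set[str]]]] = {}
    manifest: dict = {"planted": {}, "null_terms": [f"NULL:{i}" for i in range(n_null_terms)]}
    odds0 = baseline_prob / (1 - baseline_prob)
    for s in range(n_species):
        species = f"species_{s + 1:03d}"
        background = {f"{species}_prot{i + 1:04d}" for i in range(background_size)}
        study = set(sorted(background)[:study_size])
        annotations: dict[str, set[str]] = {p: set() for p in background}
        for plant in cfg.planted_enrichment:
            if s >= plant.n_species:
                continue
            odds1 = plant.odds_ratio * odds0
            p1 = odds1 / (1 + odds1)
            for protein in sorted(background):
                prob = p1 if protein in study else baseline_prob
                if rng.random() < prob:
                    annotations[protein].add(plant.term)
            manifest["planted"][plant.term] = {
                "odds_ratio": plant.odds_ratio,
                "p_study": p1, "p_background": baseline_prob,
            }
        for term in manifest["null_terms"]:
            for protein in sorted(background):
                if rng.random() < baseline_prob:
                    annotations[protein].add(term)
        species_data[species] = (study, background, annotations)
    return species_data, manifest


def _sample_score(rng: Random, pathogenic_frac: float, benign_frac: float) -> float:
    u = rng.random()
    if u < pathogenic_frac:
        return rng.uniform(0.9000001, 1.0)
    if u < pathogenic_frac + benign_frac:
        return rng.uniform(0.0, 0.0999999)
    return rng.uniform(0.1, 0.9)


def generate_scores(
    cfg: FixtureConfig,
) -> tuple[list[PathogenicityRow], list[PeptideHit]]:
    """Score rows for a synthetic protein with one quasi-prime locus.

    Inside-locus scores have the configured pathogenic (> 0.9) mass; the
    benign (< 0.1) mass of each arm mirrors the pathogenic mass of the other
    arm, so inside skews pathogenic and outside skews benign. Returns the rows
    and the single synthetic hit defining the locus.
    """
    mix = cfg.patho_mixture
    if mix is None:
        raise ValueError("patho_mixture is not configured")
    if mix.n_inside < 1 or mix.n_outside < 1:
        raise ValueError("n_inside and n_outside must both be >= 1")
    rng = Random(cfg.seed + 2)
    locus_len = 200
    protein_len = 1000
    protein_id = "SYNPROT1"  # synthetic stand-in protein, not a UniProt entry
    hit = PeptideHit(peptide="A" * locus_len, proteome_id="SYN",
                     protein_id=protein_id, start=1, end=locus_len)
    rows: list[PathogenicityRow] = []
    for _ in range(mix.n_inside):
        rows.append(PathogenicityRow(
            protein_id=protein_id,
            position=rng.randrange(1, locus_len + 1),
            alt_residue=rng.choice(CANONICAL_AA),
            score=_sample_score(rng, mix.inside_pathogenic_fraction,
                                mix.outside_pathogenic_fraction)))
    for _ in range(mix.n_outside):
        rows.append(PathogenicityRow(
            protein_id=protein_id,
            position=rng.randrange(locus_len + 1, protein_len + 1),
            alt_residue=rng.choice(CANONICAL_AA),
            score=_sample_score(rng, mix.outside_pathogenic_fraction,
                                mix.inside_pathogenic_fraction)))
    return rows, [hit]
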