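# quasiprime

Discovery and analysis of **taxonomic quasi-primes**: peptide k-mers that are
present in at least one reference proteome of a taxon (superkingdom, kingdom
or phylum) and absent from every proteome outside it. Such k-mers are
sequence fingerprints of a lineage — useful as taxonomic markers, as probes
of lineage-specific adaptation, and as pointers to functionally critical,
disease-relevant protein loci.

The package is aimed at computational biologists working with UniProt-style
reference proteome collections who want to call taxon-exclusive peptides,
quantify how conserved they are, and run the downstream analyses that give
them biological meaning.

## The quantities at the core

For a k-mer $K$ and a taxon $T_i$ with $|T_i|$ reference proteomes, the
**ε-score** is the percentage of the taxon's proteomes containing $K$:

$$\varepsilon_K^{T_i} = \frac{|\{P \in T_i : K \in P\}|}{|T_i|} \times 100$$

ε = 0 means complete absence and ε = 100 universal presence. The set of
**taxonomic quasi-primes** of $T_i$ is

$$Q_{T_i} = \{K : K \in T_i \ \wedge\ \forall j \neq i,\ K \notin T_j\}$$

i.e. k-mers present somewhere in $T_i$ and absent from every proteome outside
it. Proteomes unassigned at a rank count as "outside every taxon": their
presence vetoes exclusivity, and they are excluded from every denominator.

Around this core the package provides:

* **k-mer indexing** (`quasiprime.kmers`) — canonical-residue k-mer
  extraction and a prefix-sharded presence index (k-mer → proteome set).
* **Quasi-prime calling and summaries** (`quasiprime.core`) — per-taxon
  records with ε, and per-taxon counts with median (ε_M) and maximum (ε_max).
* **Peptide matching and classification** (`quasiprime.matching`) — an
  Aho–Corasick automaton mapping peptides to 1-based inclusive protein
  coordinates, plus per-taxon prefix tries of consensus patterns that assign
  a novel proteome to its most probable lineage via an ε-weighted score.
* **Substitution neighborhoods** (`quasiprime.neighborhood`) — all
  single-residue variants with a strictly positive BLOSUM62 score
  ("biologically conservative" variants), their corpus mapping, and bracket
  consensus patterns such as `[LM][FW][DEN]CM[EKQ][ILV]`.
* **Enrichment meta-analysis** (`quasiprime.enrichment`) — per-species
  Fisher exact tests with Haldane–Anscombe-corrected odds ratios, combined
  across species with a DerSimonian–Laird random-effects model (Cochran's Q,
  τ²) and Benjamini–Hochberg correction.
* **GO term clustering** (`quasiprime.ontology`) — Wang semantic similarity,
  average-linkage clustering at namespace-specific thresholds, representative
  term selection and winsorized weighted LORs.
* **Pathogenicity overlap** (`quasiprime.pathogenicity`) — KS statistic,
  Cliff's delta, benign/pathogenic class fractions (score < 0.1 / > 0.9) and
  the fold enrichment of pathogenic variants inside quasi-prime loci.
* **Synthetic fixtures** (`quasiprime.simulate`) — seeded corpora with
  planted taxon-exclusive peptides (exact ground truth after collision
  repair), planted annotation enrichments, and two-population pathogenicity
  score mixtures.

## Worked example

```python
from quasiprime import (FixtureConfig, PlantSpec, generate_corpus,
                        build_presence_index, call_quasiprimes, summarize,
                        conservative_variants, consensus_pattern)

cfg = FixtureConfig(seed=7, planted_quasiprimes=[
    PlantSpec("phylum", "Chordata", presence_fraction=0.75),
    PlantSpec("phylum", "Chordata", presence_fraction=1.0),
    PlantSpec("phylum", "Arthropoda", presence_fraction=0.5),
])
corpus, taxonomy, manifest = generate_corpus(cfg)
records = list(call_quasiprimes(build_presence_index(corpus, k=7),
                                taxonomy, "phylum"))
planted = {m.peptide for m in manifest.planted}
for rec in records:
    if rec.kmer in planted:
        print(f"{rec.kmer}  {rec.taxon:<10}  eps = {rec.epsilon:.2f} "
              f"({rec.n_present}/{rec.n_taxon} proteomes)")
```

prints

```
HYPGTKR  Arthropoda  eps = 50.00 (4/8 proteomes)
RQNWHSF  Chordata    eps = 75.00 (6/8 proteomes)
WMHWDLF  Chordata    eps = 100.00 (8/8 proteomes)
```

— the three planted peptides come back as quasi-primes of their taxon with ε
exactly matching the planted presence fraction (e.g. 6 of 8 Chordata
proteomes → ε = 75). `summarize(records)` then reports per-taxon counts with
ε_M and ε_max; on this corpus the Chordata ε_max is 100.00 (the universally
planted marker), with the remaining ~18k records being background k-mers each
private to a single proteome (ε_M = 12.50, i.e. 1/8).

The substitution neighborhood of the Chordata marker `MWDCMEV`:

```python
vset = conservative_variants("MWDCMEV")
print(len(vset))  # 16 variants with a positive BLOSUM62 score
retained = {"LWDCMEV", "MFDCMEV", "MWECMEV", "MWNCMEV",
            "MWDCMKV", "MWDCMQV", "MWDCMEI", "MWDCMEL"}
print(consensus_pattern("MWDCMEV", retained).render())
# [LM][FW][DEN]CM[EKQ][ILV]
```

The same pipeline is scriptable from the shell via the `qprime` CLI
(`qprime simulate`, `index`, `call`, `match`, `classify`, `variants`,
`enrich`, `combine`, `patho`); every stage reads and writes plain TSV/FASTA.

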