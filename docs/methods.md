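# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about real
proteome corpora.

## Quasi-prime calling

A presence index maps each k-mer to the set of proteomes containing it at
least once; multiplicity within a proteome is ignored, because the ε-score is
a fraction of proteomes, not of occurrences. K-mers are extracted only from
windows made of the 20 canonical amino acids: ambiguity codes (X, B, Z, J),
stop characters (`*`) and the non-standard residues U/O break the window but
not the whole protein, so a single ambiguous residue costs at most k windows
of signal. U and O are excluded for consistency with the substitution
analysis, which is defined over the canonical-20 BLOSUM62 block.

A k-mer is called a quasi-prime of taxon T at a rank iff every proteome
containing it carries the label T at that rank. Proteomes with an empty label
at the rank are treated as *outside every taxon*: if one contains the k-mer,
no call is made at that rank (exclusivity cannot be certified against an
unknown lineage), and unassigned proteomes never enter a denominator. A
k-mer may be a quasi-prime at several ranks simultaneously; ranks are called
independently.

Summary statistics per (rank, taxon) are the quasi-prime count, the median
ε-score ε_M (even-sized lists: mean of the central pair) and the maximum
ε_max.

The index is sharded by k-mer prefix (default length 2, 400 shards) and
traversed in lexicographic order, so shard files are byte-stable and the
k-mer space is partitioned exactly. At the corpus sizes used in the test
suite everything fits in memory; the shard structure is what makes larger
corpora tractable, since 20⁷ ≈ 1.28 × 10⁹ possible seven-mers preclude a
naive single map.

## Peptide matching and trie classification

Peptide-to-protein mapping uses an Aho–Corasick automaton: all peptides are
matched in a single pass per protein, overlapping occurrences included.
Coordinates are 1-based and inclusive (a seven-mer starting at residue 111
spans 111–117).

For classifying a novel proteome, each taxon's marker patterns (exact
peptides or bracket consensus patterns) are held in a prefix-tree structure
whose edges carry residue alternatives. The likelihood score is
artifact-defined — the idea of an ε-weighted profile is established but no
canonical formula exists — and is implemented as

    score(T) = Σ_{matched patterns p of T} log1p(ε_p / 100) / |patterns(T)|

The log1p damps the influence of very high-ε patterns; normalization by
pattern-set size prevents taxa with large marker sets from winning by volume.
Ties break to the lexicographically smallest taxon; below a minimum number of
total hits (default 1) the result is "unclassified" rather than an argmax
over an all-zero profile. The scoring function is deliberately isolated so
alternatives can be substituted.

## Substitution neighborhoods

A variant is *biologically conservative* when it differs from the seed at
exactly one position and the substitution scores **strictly greater than
zero** in BLOSUM62 (score 0 is not favorable). This strict reading
reproduces all five published variant counts for the conserved Chordata
seven-mers (MWDCMEV 16, HEQCCWT 11, CCEEWVC 11, CPKRCVC 8, CCTPHRT 6).
The matrix is embedded as a constant half-bit integer table to remove
dependency drift; the unit tests cross-check every entry against Biopython's
copy. Consensus patterns render one residue set per position, brackets
sorted alphabetically, singletons bare.

## Enrichment and random-effects combination

Per species, each annotation term observed in the study set (the quasi-prime
containing proteins) yields a 2×2 table against the species' full background.
The odds ratio, its log (LOR) and SE use the Haldane–Anscombe correction
(+0.5 on all four cells, applied unconditionally), so zero cells stay finite;
the p-value is a two-sided Fisher exact test on the raw integer cells — the
correction is a property of the effect estimate, not of the exact test.
`fisher_p` sums hypergeometric probabilities not exceeding the observed
table's (relative tie tolerance 1 + 1e-13, which absorbs floating-point ties
that exact rational arithmetic would count as equal). Study counts are never
propagated up the ontology graph, and background term counts use direct
annotations only. In GO mode, species with ≤ 10 study proteins are skipped;
in protein-entry mode, per-species results are pre-filtered to p < 0.05 and
OR > 1 before combination, and single-species entries that pass the filter
are retained without combination.

Cross-species combination is a DerSimonian–Laird random-effects model: fixed
weights w_i = 1/SE_i², Cochran's Q, τ² = max(0, (Q − df)/C) with
C = Σw − Σw²/Σw, adjusted weights 1/(SE_i² + τ²). The combined effect is
tested with z = LOR̂/SE against a t distribution with n − 1 degrees of
freedom (floored at 1; a single study passes through with Q = τ² = 0 and its
own LOR/SE). DL is the standard moment estimator and is used here as the
named choice wherever "Q and τ²" are invoked without an estimator.
Benjamini–Hochberg correction is applied within one analysis family (one
rank × mode × term-class combination) at a time.

## GO clustering

Wang similarity propagates an S-value of 1 from each term up its ancestor
graph, multiplying per edge by a relation factor (is_a 0.8, part_of 0.6 — the
measure's canonical weights) and taking the maximum over paths; the
similarity of two terms is the sum of both S-values over shared ancestors
divided by the sum of all S-values of each term. Distances 1 − similarity
feed average-linkage agglomerative clustering, cut at 0.54 (BP), 0.535 (MF)
and 0.52 (CC). These thresholds are interpreted as *distance* cutoffs; the
alternative (similarity cutoffs) would invert the clustering granularity and
is incompatible with the cited threshold magnitudes. Singleton clusters are
retained only when the term's adjusted p < 0.05. Cluster representatives
order by (adjusted p ascending, presence percentage descending, combined LOR
descending, term id ascending). The cluster effect is an inverse-variance
weighted LOR after upper-tail winsorization at the 95th percentile (linear
interpolation); winsorization is one-sided because its purpose here is to cap
extreme positive enrichments, and the analysis pipeline only feeds enriched
(OR > 1 dominated) terms.

## Pathogenicity overlap

Scores are partitioned by strict thresholds — benign < 0.1, pathogenic >
0.9; scores in [0.1, 0.9] contribute to KS and Cliff's delta but to neither
class. The comparison is restricted to proteins that contain at least one
quasi-prime hit, so "outside" means "elsewhere in the same proteins", which
is the implemented baseline for the fold enrichment
fold = frac_pathogenic(inside) / frac_pathogenic(outside); a zero outside
fraction reports NaN rather than a number. KS uses the exact sup-norm
statistic with the asymptotic two-sided p; Cliff's delta is computed by
binary search over the sorted second sample (identical to the O(n·m)
definition, verified against it in tests).

## Synthetic data

The generator draws background residues uniformly over the 20 canonical
amino acids from `random.Random` (integer state only), so a seed determines
the corpus byte-for-byte on any platform. Planted peptides are inserted into
⌈f·n⌉ of a taxon's n proteomes; the corpus is then re-scanned and any chance
occurrence of a planted peptide outside its assigned proteome set is
rewritten with fresh residues, iterating to a fixed point. The planted
manifest is therefore *exact* ground truth: recovery tests assert equality,
not approximation. Annotation fixtures plant a term at a target odds ratio by
solving odds(p_study) = OR × odds(p_background) for the study annotation
probability; null terms are annotated independently of study membership.
Pathogenicity fixtures draw from a three-part mixture (pathogenic mass
uniform on (0.9, 1], benign mass uniform on [0, 0.1), remainder uniform on
[0.1, 0.9]); the benign mass of each arm mirrors the pathogenic mass of the
opposite arm, giving the characteristic inside-pathogenic / outside-benign
skew.

What the fixtures do **not** emulate: realistic residue composition,
homology and phylogenetic correlation between proteomes, protein-length
distributions, annotation co-occurrence structure, or position-dependent
pathogenicity. Passing tests therefore establish correctness of the
algorithms under their stated definitions and recovery of planted effects —
not performance on real UniProt corpora, whose headline values (e.g. a
seven-mer at ε = 98.11% in Eukaryota, 2,652 conserved Chordata seven-mers, a
2.08-fold pathogenic enrichment) require the full 24,073-proteome reference
set and proteome-wide variant-effect maps. Those figures are covered at desk
scale by structural analogues: exact recovery of a planted ε = 98 marker,
brute-force-verified exclusive k-mer counts, and recovery of planted fold
shifts {1, 2, 4} within 3 SE at 10,000 variants per arm.

## Problem sizes and calibration choices

The test suite uses corpora of up to ~60 proteomes × 20 proteins × 120
residues, 100-corpus oracle-equivalence sweeps at k ∈ {3, 4, 5}, an
exhaustive Fisher comparison over all 2×2 tables with margins ≤ 30, and
10,000 variants per arm for pathogenicity recovery. Null calibration of the
Fisher test uses a background of 2,000 proteins, a study of 200 and a
baseline annotation probability of 0.3 over 2,000 null terms: margins large
enough that the exact test's discreteness leaves the nominal 5% rejection
rate inside a 3-SE binomial band. With small margins the Fisher test is
conservative and no generator setting can (or should) make it exactly
calibrated.

## Known limitations

* The exact formula behind the published "modified z-score" is not public;
  the t-referenced z of the DL model is the declared implementation.
* The trie classifier's likelihood score is artifact-defined (see above);
  accuracy claims are validated only on planted, collision-free fixtures.
* Variant mapping infers the seed's taxon from where the seed occurs; for
  seeds absent from the corpus the taxon must be given explicitly.
* The external-memory shard path aggregates in memory per run; truly
  out-of-core aggregation (merge passes over spill files) is not implemented.
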