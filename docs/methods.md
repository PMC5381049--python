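# Methods

This note records what `nlscan` computes, the assumptions baked into each
stage, the defaults and why they were chosen, and what the synthetic data
do and do not establish about real proteomes.

## Motif dialect and matching

Motifs are parsed into an element list (literal / wildcard / residue-class,
each with a repeat range).  Matching semantics:

* A wildcard (`.`) matches exactly the 20 standard amino-acid letters.
  Ambiguity codes (`X`, `B`, `Z`, `J`), `U`/`O` and `*` in sequences match
  nothing — neither wildcards nor literals — so every reported match is a
  concrete, biologically interpretable peptide.  Sequences are uppercased
  and stop marks stripped on read.
* At each start offset the scanner reports at most one span: the shortest
  matching expansion.  Overlaps across offsets are allowed.  Downstream
  counting only asks whether a protein has ≥ 1 match, so this convention
  cannot change any abundance number; it exists to make the matcher's
  output well-defined and oracle-checkable.  The implementation is a small
  dynamic programme over reachable offsets, equivalent to enumerating every
  concrete expansion and keeping the earliest/shortest — the test suite
  verifies that equivalence against two independent brute-force oracles
  (full string enumeration with substring search where the expansion count
  is bounded; recursive repeat-shape enumeration otherwise).
* The typographic ellipsis `…` that appears in one published motif
  (`TKRS…M`) is normalised to three wildcards.  This is the only reading
  consistent with that motif's published length of 8.
* **Nominal length** of a variable-length motif is the midpoint of its
  (min, max) span, rounded half-up.  This is the only convention that
  reproduces the published lengths 25 for
  `K[RK]{3,5}.{11,18}[RK]K.{2,3}K` (span 20–30) and 31 for
  `[KR]{4}.{20,24}K{1,4}.K` (span 27–34).

The shipped motif list (`src/nlscan/data/nls_motifs.txt`) holds the 16
curated NLS-like motifs used throughout: eleven fixed monopartite motifs,
three with wildcard spacers and two bipartite patterns.

## Abundance

"Abundance" counts **bearing proteins**, not match occurrences: a protein
with five occurrences of a motif counts once for that motif, and a protein
matching several motifs counts once per motif but only once in the strain
total M_i (union semantics).  Per-strain "motif types" is the number of
motifs with a nonzero bearing count.  These choices make the abundance
matrix permutation-invariant and additive: adding a protein that matches
motif m increments exactly counts[m] and M_i.

## Q normalization

Q_i = M_i / log10(N_i · G_i), with N_i the gene count and G_i the genome
size in bp.  The logarithm is base 10 ("lg" in the usual biological
reading), which puts genome-scale denominators in the range ~9–12 and
yields well-scaled Q values.  Matrix normalization applies the same
denominator to each strain's column, motif by motif.  The denominator is
required positive (N·G > 1); a zero gene count is rejected at metadata
parse time.

## Complexity score

`composite = length + diversity + origin`, an unweighted sum — the three
components are published per motif but no combination rule is, and the
score's only use is ordering motifs from simple to complex, which an
unweighted sum serves transparently.

* **Diversity** = number of distinct residue letters in literals and
  classes, +1 per wildcard element, +0.5 per class element.  This is the
  published rule as stated.  It does not reproduce every published cell:
  `RKRKK` (two residue types) is published as 3, and `TKRS…M` as 11,
  neither of which the stated rule can yield.  The rule is implemented as
  written and those cells documented as irreconcilable rather than
  reverse-fitted.
* **Origin** takes planctomycetes as the control (0).  A motif detected in
  at least one eukaryotic strain scores 5 + (mean abundance over all
  eukaryotic strains, zeros included)/10.  A motif found only in
  non-planctomycete prokaryotes scores −5 regardless of abundance; archaea
  are treated as non-planctomycete prokaryotes here.  A motif present in
  both planctomycetes and other bacteria (but no eukaryote) stays at the
  control value 0, since the penalty as published applies only to motifs
  absent from planctomycetes.  In this package's datasets the eukaryotic
  group is fungi.

## Families

The ortholog-style grouping runs in two steps:

1. **Similarity**: cosine similarity of k-mer count vectors (default k=3),
   edges kept at weight ≥ 0.5.  This replaces reciprocal-BLAST scores with
   a deterministic, dependency-free, alignment-free measure; the backend is
   pluggable (`mcl` accepts any weighted graph).  k=3 gives a 8000-dim
   profile that is effectively orthogonal between unrelated random
   sequences yet retains ~85% overlap at 5% point mutation, so the 0.5
   threshold cleanly separates planted families from background.
2. **MCL**: self-loops set to each node's maximum incident edge weight
   (1.0 for isolated nodes), column normalization, then alternating
   expansion (matrix squaring) and inflation (entrywise power 2.0, the
   conventional default, then renormalization) until the largest entry
   change is < 1e-6 or 200 iterations.  Clusters are read off attractors;
   attractor systems sharing a node are merged, and family ids are
   assigned in lexicographic order of each family's smallest member, so
   the partition is deterministic for any input order.

Single-member families are flagged orphans and excluded from group-sharing
(Venn) counts.  Cross-group families are classified by motif conservation:
same motif set in every group; different sets among prokaryotes only; or
different sets in a family reaching archaea/eukaryotes.  The composite
complexity range across a family's motifs exposes complexity shifts at
group boundaries.

## Ordination and gradient

PCA centers motif dimensions (no variance scaling — all entries share
units after Q normalization) and decomposes by SVD, with the largest-
magnitude loading of each component made positive so signs are
reproducible.  With all components kept, score distances reproduce
centered-profile distances to numerical precision; the test suite checks
this identity at 1e-8 relative tolerance and cross-checks scores against an
independent PCA implementation.

The gradient test itself deliberately does **not** use PC-truncated
coordinates: group distances to the fungal centroid are measured in the
full normalized-profile space, avoiding an arbitrary component cutoff.
Verdict "gradient" requires the bacteria-group mean distance to strictly
exceed the planctomycete mean.

## Synthetic data

`generate_strain` draws background proteins residue-wise from a fixed
composition (default: uniform over the 20 residues with K and R
down-weighted ×0.5, renormalized — keeping accidental basic-cluster hits
rare), then plants Poisson(λ_m) distinct carrier proteins per motif, one
sampled expansion each (repeat counts uniform over their ranges, class and
wildcard residues uniform) overwritten at a uniform offset.  Carriers are
disjoint across motifs, which keeps planted motif sets unambiguous; motif
co-occurrence in one protein is not simulated.  Protein lengths are
truncated-normal (default mean 160, sd 40, min 60 — the minimum must exceed
the longest motif span plus 2).

Exact ground truth is enforced by rescanning: background proteins matching
any motif, and carrier proteins matching anything beyond their planted
motif, are regenerated (up to 100 attempts; a degenerate background such as
poly-K raises an error).  Carrier rescanning matters: a planted basic
cluster plus accidental downstream background lysines can otherwise
complete a bipartite pattern and break truth-vs-scan equality.  The NES
consensus is not part of the screened set, so NES background hits do occur
and are reported as such.

Two presets ship.  The **gradient preset** (three groups, 5 strains/group,
100 proteins/strain) sets the planctomycete rate profile to exactly
0.5·bacteria + 0.5·fungi, so the distance gradient is recoverable by
construction; bacterial rates are concentrated on simple monopartite
motifs (≈12 expected carriers/strain) and fungal rates span all motif
classes (≈48/strain).  The **study preset** adds archaea and
presence/absence structure: two motifs private to planctomycetes, three to
fungi, one shared by non-planctomycete bacteria and fungi only, and a
bipartite motif present in all groups.  Metadata (genome size, gene count)
is drawn uniformly from group-typical ranges (bacteria 3–6 Mb, fungi
25–40 Mb, etc.).

`generate_family_fixture` plants protein families as point-mutated copies
(rate 0.05) of random ancestors, distributed across groups per an explicit
design, for clustering and sharing tests.

**What the synthetic data do not emulate**: real amino-acid composition
biases, homology between background proteins, paralogy, motif positional
preferences (termini vs. core), genome-size/abundance correlations, and
incomplete proteome prediction.  Passing tests therefore establish that
the pipeline's algebra and algorithms are correct and that planted signal
of realistic magnitude is recovered — not that any biological claim holds
for real proteomes.

## Problem sizes and numerical choices

Tests and the acceptance script run studies of 3–17 strains × 100 proteins
(chosen to exercise every code path with comfortably separated planted
effects), 100 seeded replicates for gradient recovery, 20 seeds for exact
truth recovery, and 1000 mixed random/planted sequences for matcher/oracle
equivalence.  Floating-point TSVs are written at 6 significant digits;
MCL convergence tolerance is 1e-6 with an interpretation threshold of 1e-5
on the steady-state matrix; PCA drops components with singular value below
1e-9 of the leading one.  All randomness flows through
`numpy.random.default_rng` seeded from a single study seed (per-strain
seeds are spawned `SeedSequence` children), so identical seeds give
byte-identical outputs.

## Known limitations

* The k-mer similarity analogue is not calibrated against BLAST bit scores;
  absolute family counts on real data would differ from an OrthoMCL run
  even if the partition logic is identical.
* The diversity rule cannot reproduce two published score-matrix cells (see
  above); the discrepancy is inherent to the published rule, not a bug.
* The origin score depends on which strains are in the study (it reads
  presence and fungal mean abundance from the abundance matrix), so
  composites are comparable only within one study.
* `AbundanceMatrix.from_tsv` cannot recover true union totals M_i from a
  counts matrix alone and substitutes column sums (an upper bound); the
  pipeline keeps exact totals when scanning in-process, and the analysis
  scripts pass the exact totals through the summary table.
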