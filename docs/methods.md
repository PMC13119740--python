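# Methods

## Problem setting

A genebank collection is modelled as an accession × marker matrix of
biallelic SNP calls in four canonical states: homozygous reference,
homozygous alternate, heterozygous, missing. The task is to find a small
ordered marker panel whose joint calls give each accession a unique
multilocus fingerprint, then to use that panel for duplicate detection,
regeneration QC/QA matching, and to quantify how the panel degrades when
assays fail.

## Discrimination predicate

Two accessions are distinguished *by one marker* when their calls at that
marker differ informatively. Two policies are provided:

- **STRICT** (default): only opposite homozygotes distinguish. Inbred
  cereal material is nearly fully homozygous and the heterozygote cluster is
  the least reliable part of a fluorescence-based KASP readout, so a
  HET-vs-HOM difference is not trusted as evidence of distinct identity.
- **GENOTYPIC**: any two distinct non-missing states distinguish — suitable
  when the three-cluster readout is trusted, e.g. for outbred or clonally
  propagated material.

A missing call never distinguishes under either policy: a no-call is an
absence of evidence, and treating it as evidence would let assay dropouts
manufacture spurious "unique" accessions.

## Greedy selection

Selection operates on the set of unresolved accession pairs (n(n−1)/2
initially).

1. Forced markers (already-validated assays) are seeded first, in the order
   given, consuming the pairs they resolve. Panel augmentation for a new
   population is exactly selection with the existing panel force-included.
2. If no pair has yet been resolved, the first greedy pick is the
   highest-MAF candidate — the marker that splits the population most
   evenly. One deliberate refinement: the highest-MAF rule is applied only
   among candidates with positive incremental discrimination, so a marker
   that resolves nothing (e.g. an all-heterozygous marker under STRICT,
   which can still have MAF 0.5) is never seeded. On data where the
   MAF-leader actually splits the population — all non-degenerate inputs —
   this coincides with the plain highest-MAF rule.
3. Every later pick maximises *incremental discrimination*: the count of
   still-unresolved pairs the candidate resolves. The loop ends when no
   pairs remain, no candidate adds a pair, or `max_markers` is reached.

Ties (on MAF or on incremental counts) are broken by marker input order,
the only tie-break that is total, reproducible and data-independent; with a
fixed input the selection is fully deterministic.

Markers in complete LD (r² = 1) with a selected marker duplicate its
partition of the accessions and therefore always score zero incremental
discrimination; LD redundancy needs no explicit filter. Pairwise r² is
still reported post hoc (squared Pearson correlation of ALT-dosages over
pairwise-complete accessions) for panel documentation.

Internally the unresolved-pair set is a symmetric boolean matrix and
per-candidate counts are computed with float32 matrix products (exact for
counts far below 2²⁴), giving O(n²·m) work per step; the pair-level contract
is independently checked in the tests against the atomic predicate
enumerated pair by pair. Greedy set cover is not guaranteed minimal; on
small instances (≤ 15 markers, ≤ 12 accessions) an exhaustive-search oracle
in the test suite verifies the greedy panel is always a valid discriminating
set, never smaller than the true optimum, and frequently attains it.

## Fingerprint grouping

With missing calls the cannot-distinguish relation need not be transitive
(an all-missing accession is indistinguishable from everything). Duplicate
groups are therefore defined as connected components of that relation.
Components that contain an internally *resolved* pair — held together only
through missing-heavy bridge rows — are flagged in the duplicate report so a
curator re-genotypes rather than merges. An accession is *unique* iff it is
distinguished from every other accession, i.e. its component is a
singleton; the discrimination rate is 100 × unique/total, reported to two
decimals with half-up rounding (matching how such percentages are
conventionally printed).

Registry matching compares a query call vector to registered fingerprints
only where both calls are non-missing; a verdict is MATCH/MISMATCH around a
mismatch tolerance (default 0 — any discrepancy triggers a re-test) and
AMBIGUOUS when fewer than `min_informative` comparisons were possible. The
best-matching other registry entries are always reported, since recovering
a swapped identity is the point of molecular labelling.

## QC filters

Markers are kept when call rate > `min_call_rate` (default 0.95) and MAF >
`min_maf` (default 0.05); accessions when call rate > 0.995 and
heterozygous fraction < 0.001. All comparisons are strict, following the
usual ">95%", ">5%", "<0.1%" phrasing of such thresholds; boundary values
are removed. MAF is computed from integer allele counts (a heterozygote
contributes one allele of each) so boundary comparisons are exact in
floating point. The heterozygosity denominator is the accession's
non-missing calls — missing calls carry no genotype information. Each
removed item records one primary reason, the first failing test in the
order call rate → MAF (markers) / heterozygosity (accessions) →
monomorphism; all-missing markers are classed MONOMORPHIC to keep the
reason enumeration closed. Filtering is idempotent and order-insensitive;
no imputation and no LD pruning are performed.

## Robustness simulation

Assay failures are marker-wise, so the simulation deletes k random panel
markers (uniformly, without replacement) and recomputes the discrimination
rate on the remainder; defaults are k = 1 … n−1 with 200 replicates per
level, with the exact k = 0 rate (sd 0) as baseline. Summary statistics are
the mean and the sample standard deviation (n−1 denominator). Each
(k, replicate) uses an independent RNG substream keyed on (seed, k,
replicate), so results are bit-reproducible and independent of iteration
order. Removing markers can only merge fingerprint groups, so every single
draw's rate is bounded by the full-panel rate (deterministic dominance),
and replicate means are non-increasing in k in expectation; the test suite
checks both empirically. Per-marker resolved-pair matrices are bit-packed
into uint64 words so each draw is an OR-reduce, keeping 200 × (n−1)
replicates on a 500-accession panel under a second.

## Synthetic data generator

The generator emulates the structure of an inbred cereal genebank
collection, not any particular dataset:

- **Subpopulation structure.** Ancestral reference-allele frequencies are
  uniform on `ancestral_maf_range` (default 0.05–0.5, i.e. post-QC-style
  markers). Subpopulation frequencies follow a Balding–Nichols draw,
  Beta(p(1−F)/F, (1−p)(1−F)/F), with a single Fst-like `divergence` knob
  (default 0.15, moderate differentiation among landrace/cultivar strata);
  at F = 0 subpopulations equal the ancestral frequencies exactly.
- **Inbred lines** draw one allele per marker from their subpopulation
  frequency and are homozygous for it — marginally equivalent to repeated
  selfing, and much simpler. Residual heterozygosity is then flipped in at
  `residual_het_rate` (default 0.001, the 0.1% ceiling used when filtering
  for highly homozygous material).
- **Planted duplicates** are exact copies made after heterozygosity but
  before missingness, so a duplicate pair differs only through independent
  no-calls — the situation a duplicate-detection test must recover.
- **Pedigree groups** share a common parent genotype and redraw alleles at
  a fixed random subset of segregating markers. The default of 40
  segregating markers per group reflects that sibling breeder lines differ
  at many loci genome-wide on a ~1000-marker chip; small values model
  near-isogenic material that deliberately falls below panel resolution.
- **Missingness** is uniform at `missing_rate` (default 0.002, emulating a
  post-QC training matrix whose accessions exceed a 99.5% call rate; set
  0.028–0.051 to emulate raw KASP fingerprinting runs) plus an optional
  whole-marker dropout mode, since real assay failures kill whole columns.
- **Wild populations** are sampled as a founder per collection site plus
  4–10 progeny; progeny redraw each marker from the population frequency
  with probability `within_pop_diversity` (0 → identical progeny). Site
  divergence defaults higher (0.3) than the domesticated panel, mirroring
  the sharp geographic differentiation of wild cereal populations.

Everything is keyed on one seed; identical configurations reproduce
matrices bit for bit.

What the generator does *not* model: linkage/recombination maps (markers
are independent given subpopulation frequencies), coalescent ancestry,
geographic spatial structure, genotype-calling error beyond no-calls, and
ascertainment of array SNPs. Tests passing on this generator therefore
demonstrate correctness of the algorithms and bookkeeping under the stated
population structure, not distributional fidelity to any real collection.

## Numerical conventions and degenerate inputs

- Percentages: two decimals, half-up. Reported marker statistics: three
  decimals (full precision internally).
- All-missing markers have undefined (NaN) frequency statistics, never 0.
- r² entries are NaN where a marker is constant within the
  pairwise-complete subset; the diagonal is 1 for varying markers.
- An empty matrix filters to an empty result with a warning; selection on
  an empty matrix is a configuration error.
- A single-accession population is trivially 100% discriminated; a
  single-marker panel admits no removal levels beyond k = 0.
- Letter dialects map A→HOM_REF, B→HOM_ALT; nucleotide dialects take the
  reference allele from marker metadata when supplied, otherwise the
  alphabetically first observed allele (deterministic). File orientation is
  never guessed — the dialect must state it, because silent transposition
  is a worse failure mode than an error.

## Problem sizes used in the test and acceptance runs

Oracle-equivalence checks run on 200 random instances of ≤ 12 accessions ×
≤ 15 markers, where exhaustive subset search is cheap. End-to-end and
robustness checks use synthetic panels of 200–500 accessions × 500–2000
markers — the package's own choice of a scale that exhibits all the planted
structure while keeping the whole suite fast.

## Known limitations

- Greedy panels are near-minimal, not provably minimal; the log₂ bound and
  the small-instance exhaustive audit bracket the gap.
- No probabilistic identity statistics (match probabilities given allele
  frequencies); matching is exact-count based.
- Multi-allelic markers are out of scope; PIC and the dosage coding assume
  biallelic SNPs.
- Genetic-map-aware marker spacing ("genomic coverage") is not optimised;
  forced inclusion is the supported mechanism for curated spacing choices.
- The missing-compatible grouping rule is conservative: heavy missingness
  deflates discrimination rates rather than inflating them.
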