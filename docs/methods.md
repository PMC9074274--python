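# Methods

This note documents the models and procedures implemented in `mixcat`, the
parameters that matter, the design decisions taken where the choice was
genuinely open, and what the synthetic benchmark does and does not show.

## Clustering core

Redundancy removal operates on protein sequences.  The criterion is
pairwise: member *m* joins the cluster of representative *r* when the
optimal local alignment of *m* against *r* has

* identity ≥ `min_seq_id` (default 0.95), where identity = exact-match
  columns / all aligned columns (gap columns included), and
* member coverage ≥ `min_member_cov` (default 0.95), where coverage is the
  fraction of *m* spanned by the alignment.

Coverage is asymmetric by design: it is measured on the member, so a
fragment is fully "covered" by its full-length homolog and joins its
cluster, while two non-overlapping fragments of the same gene do not
satisfy the criterion against each other and stay separate.  The 95%
identity grain targets the species level — conspecific prokaryotic strains
generally exceed 95% average amino-acid identity — so a catalogue entry
stands for a species-level gene variant cluster.

Alignment is BLOSUM62 with BLAST-style affine gap costs (a gap of length
*k* costs 11 + *k*); matrix and penalties are configurable in
`ClusterParams`.  The underlying alignment engine is
`Bio.Align.PairwiseAligner` in local mode; identity and coverage are
derived by walking the aligned blocks.  The alignment score is checked in
the test suite against an independent hand-written Gotoh
dynamic-programming oracle.

**Greedy pass.**  Sequences are sorted by length, ties broken by
lexicographically smallest id so runs are bit-reproducible.  The longest
unassigned sequence seeds a cluster and absorbs every unassigned sequence
passing the criterion; this repeats until the input is partitioned.  A
single greedy pass is used rather than an internal multi-step cascade: at
the scales this package targets, exactness and testability beat indexing
tricks, and the input/output contract (length-sorted seeds, coverage on the
member) is what defines the method.  One consequence is that every member
satisfies the criterion *directly against its representative*; tools with
internal cascades can produce members transitively more than 5% diverged
from their representative, which this implementation deliberately does not.

**Prefilter.**  An optional exact k-mer prefilter (default on, k = 6)
skips candidate pairs sharing no amino-acid 6-mer.  It is
behaviour-preserving by a pigeonhole argument: a member of length L passing
both thresholds has at most ⌊0.05·columns⌋ non-identical columns and at
most ⌊0.05·L⌋ unaligned positions, so its longest exact-match run has
length at least ≈ 0.9L/(0.1L+1) ≥ 6 for every L ≥ 12 (members shorter than
`prefilter_min_len` = 12 are always aligned).  The test suite verifies
equality of prefiltered and exhaustive clustering on randomized instances.

**Cascade.**  `cascade_cluster` clusters the pooled individual-assembly
proteins first (stage 1), then the stage-1 representatives together with
the co-assembly proteins (stage 2).  Final representatives record their
origin (`from_individual` / `from_coassembly`).  Because stage-2 seeds are
again the longest sequences, a complete gene from either source displaces
fragments of the other — the mechanism that enriches the merged catalogue
for complete genes.  The same mechanism can also promote artificially long
proteins (chimeras, miscalls); the package does not attempt to detect
those.

## Completeness classification

Prodigal-style partial codes map to classes: `00` → complete, `01`/`10` →
partial, `11` → incomplete.  The mapping is total on the four codes and
anything else is an error.  On input, a `partial=XY` token is taken from
the FASTA description line; a GFF `partial` attribute takes precedence,
and a conflict between the two raises rather than guessing.

## Digital normalization

Per-read depth is the median count of the read's canonical k-mers
(k = 31 by default; min of forward/reverse-complement) in an exact count
table built from the full pooled input.  A read of depth *d* is kept with
probability min(1, `target_depth`/*d*) if *d* ≥ `min_depth`, else dropped
(defaults 70 and 2).  Counting strictly precedes filtering — a single-pass
approximation of the two-pass counting tools use, chosen because it is
deterministic and directly testable.  Paired reads are decided as a unit on
the lower mate depth.  One uniform draw per unit makes the kept set
monotone in the target under common random numbers.  Exact dictionaries
are used rather than probabilistic sketches; the package targets desk
scale, not billions of reads.

## Read-mapping evaluation

A fixed random subset of forward reads per sample (default 10,000, RNG
seed 100) is assigned to catalogue genes.  Matching is strand-insensitive
local alignment (match +2, mismatch −6, gap open −5, extend −3); a read is
accepted when its best alignment covers ≥ 80% of the read at ≥ 90%
identity — thresholds chosen to approximate a local-mode short-read
mapper's sensitivity, configurable in `MappingConfig` and recorded in run
manifests.  A read whose best score is achieved by two or more genes is
tallied as *ambiguous* and counted to no gene (feature-count convention);
mapped + ambiguous + unmapped = total per sample, and both the strict
mapped fraction and the fraction including ambiguous reads are reported.

Candidate genes are shortlisted with an exact 11-mer index and the
alignment is computed in a window around the seeded diagonals (25 bp
slack); this can only miss reads with a mismatch in every index-length
window, and an `exhaustive` mode with full all-vs-all alignment is kept as
the reference path and used in tests.

Per-gene coverage in the total metagenome is estimated as
`count · (mean read-pair length / gene length) · (total read pairs /
sampled reads)`.  The mean read-pair length is mean forward + mean reverse
length; for single-end data each read stands for a pair, i.e. 2 × the mean
read length.  Coverage bins are low [0, 50), median [50, 500),
high [500, 5000), very high [5000, 250000]; intervals are half-open on the
left edge (boundary handling is a convention choice), and estimates above
the top edge are labelled very high with a warning.

Mapping-rate curves report the cumulative mapped fraction above each gene
length cutoff, overall and stratified by completeness class or provenance;
paired per-sample rates between catalogues are compared with the two-sided
Wilcoxon signed-rank test (all-zero difference vectors are reported as
degenerate with p = 1 rather than passed to the test).

## Synthetic communities and emulated assembly

The simulator provides ground truth for end-to-end testing.  It emulates
two mechanisms that differentiate the assembly strategies, as explicit
parametric rules — assembly is *not* performed:

1. **Coverage pooling.**  Species coverage per sample is lognormal
   (median 3×, σ = 1.5) modulated by a gradient preference and sample
   noise.  A gene is individually recovered in a sample when that sample's
   coverage clears 2× (with per-gene lognormal idiosyncrasy, σ = 0.4); the
   co-assembly sees the *pooled* coverage against a 5× threshold.  Genes
   with per-sample coverage below 2× everywhere but pooled coverage above
   5× are co-assembly-only — the rescue mechanism.

2. **Strain-driven fragmentation.**  The upper 60% of species by abundance
   carry 2–4 strains with global proportions Dirichlet(3), tightly
   correlated across samples (concentration 50).  Per-gene amino-acid
   identity between strains is drawn uniformly in 0.95–0.995, realized by
   codon-level substitutions with a synonymous extra rate of 0.05.  Each
   gene has a breakpoint (its strain-divergence hotspot, uniform in the
   middle 30–70%).  The co-assembly fragments the gene there with
   probability `frag_max · H · gate` where H is the normalized entropy of
   the pooled strain mixture and the gate scales linearly with mean
   pairwise strain divergence, saturating at 1% (so zero divergence
   disables fragmentation — the negative control).  Fragments are a left
   piece (code `01`) and right piece (code `10`), each independently
   surviving with probability 0.7 and only if ≥ 30 codons.  An individual
   sample recovers the gene *complete* when its dominant strain fraction
   reaches 0.8; otherwise it recovers one side of the breakpoint —
   consistently the same side per gene (probability 0.85) and extended
   2–12% past the hotspot, since strain mixing is weaker within one
   sample; occasionally (p = 0.15) the piece loses both edges (code `11`).

Gene lengths are lognormal with median 336 bp, σ = 0.35, clipped to
150–3000 bp, so the length distribution peaks between 300 and 350 bp as in
real gene catalogues.  All genes have valid ORF structure (ATG start, TAA
stop, no internal stops) so completeness codes are meaningful.  Reads are
drawn from strain sequences proportional to coverage × strain proportion ×
gene length, with uniform starts, per-base substitution errors (0.5%), and
random strand; every read and emitted gene record embeds its truth gene id.
For coverage arithmetic each single-end read represents a read pair of
combined length 2 × read length, and the community reports its nominal
total read-pair count from the coverage model, which is what the coverage
estimator scales sampled counts up to.

**The shipped benchmark** is `SimConfig()`'s defaults: 40 species × 15
genes, 20 samples, 4000 reads per sample (mapping subsamples 1000), master
seed 0.  On this scenario the three strategies reproduce the expected
qualitative pattern: the mix catalogue holds the most nonredundant genes
and the most complete genes, the individual assembly has fewer complete
genes than the co-assembly, the mix catalogue's per-sample mapping rate
dominates both, and mapped reads on low-coverage mix genes are mostly of
co-assembly provenance while high-coverage genes are mostly individual.

## What the benchmark does and does not show

The simulator encodes the *mechanisms* (pooled rescue, strain-driven
fragmentation, longest-seed enrichment) sharply, so strategy differences
are larger than on real data — e.g. the co-assembly's mapping-rate deficit
is exaggerated because every fragmented gene loses a piece with fixed
probability, with no chance of reassembly from unmixed regions.  Ordering
margins between the individual and mix gene counts are a few percent and
depend on the random draw; they are stable for the shipped seed but not
guaranteed for arbitrary seeds, which is the expected behaviour of a
desk-scale community (hundreds of genes) against orderings the original
setting establishes with tens of millions.  Passing tests therefore show
the implementation reproduces the mechanisms and their direction, not
effect sizes on real data.  The simulator also omits: indel sequencing
errors, chimeric contigs, eukaryotic gene structure, inter-species homology
(so ambiguous mappings are rare), and any real de Bruijn graph behaviour.

## Numerical and degenerate-input conventions

* Representative ties (equal length) break to the lexicographically
  smallest id; all randomized components take explicit seeds, and two runs
  with the same config produce byte-identical outputs (manifests carry a
  config hash).
* Empty catalogues summarize to zeros; reads shorter than k pass through
  normalization with a logged warning; genes shorter than the read length
  contribute no reads; screen ids absent from a catalogue are ignored with
  a log line; annotation rows for genes outside a catalogue are kept (the
  table may serve several catalogues) and logged.
* `*` stop characters are stripped from protein termini on input;
  sequences are upper-cased.
* The cross-catalogue comparison (`compare_catalogues`) applies the
  clustering coverage rule to the tested protein by default; an
  identity-only criterion is available (`min_cov=None`), in which case the
  prefilter is disabled because its safety argument needs the coverage
  bound.  Both directions (A vs B, B vs A) are reported.
* Total-bp summaries use nucleotide lengths; amino-acid totals are not
  silently substituted.
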