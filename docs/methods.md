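# Methods

This note documents the models, estimators, conventions and numerical
choices behind `ltrconv`, and what the synthetic tests do and do not show
about real data.

## Coordinate dialect and variant representation

All coordinates are 1-based and inclusive on both ends: `chrY:10-19` spans
10 bp and a cluster's span is `end − start + 1`. BED-style inputs are
converted on read. FASTA headers of the form `chrom:start-end` (hyphen or
en-dash) anchor a sequence to the chromosome; alignment column *c* maps to
chromosome position `reference.start + (ungapped offset of c in the
reference row)`.

Indels are collapsed per run of gap-bearing columns into a single variant
anchored at the leftmost affected base, with `indel_length` the run length;
an indel counts as **one** variant and one pairwise difference regardless of
length. The missing-genotype symbol is `N`; IUPAC ambiguity codes other than
`N` are rejected (the target data is haploid, so heterozygous-looking calls
indicate a problem upstream). Variants with >20 % missing genotypes are
flagged `high-missingness` but retained, preserving counts. Columns that are
invariant among the samples but differ from the reference are reported as
*reference-specific positions* — artifacts of the reference lineage, not
polymorphisms — and excluded from all downstream counts.

## Polarization by Fitch parsimony on a fixed tree

The phylogeny is an input, never re-estimated: the analysis presumes the
tree is known from independent markers (for the MSY, the haplogroup
phylogeny). Each biallelic variant is assigned ancestral/derived states by
Fitch small parsimony:

1. Bottom-up pass builds each node's state set (missing tips are
   unconstrained and contribute the full allele set).
2. The ancestral allele is the root's state; when the root set is ambiguous
   the tie is broken by a designated outgroup tip (mirroring analyses where
   basal samples fix polarity), else by the major allele.
3. Top-down refinement assigns each node its parent's state when that state
   is in the node's set, otherwise the node's own (for biallelic characters
   this is deterministic and attains the Fitch minimum).

Each edge whose child state differs from its parent's is one mutational
event on that branch — `forward` if it introduces the derived allele, `back`
if it restores the ancestral one. A variant with >1 event is homoplasic;
`recurrent events = Σ(n_events − 1)` over homoplasic variants, giving the
identity `total events = variants + recurrent events`. Variants where some
internal node's bottom-up set is non-singleton admit multiple equally
parsimonious placements and are flagged `placement-ambiguous`; the
deterministic refinement above is used so outputs are reproducible.
Multi-allelic sites are rejected rather than guessed. Indels are polarized
exactly like SNPs (presence/absence).

## Nucleotide diversity

π is the average pairwise difference per site,
`π = [Σ_{i<j} d_ij / C(n,2)] / L`, without the n/(n−1) correction, and its
SD is the square root of Nei's (1987) sampling variance

    V(π) = (n+1)π / (3(n−1)L) + 2(n²+n+3)π² / (9n(n−1)),

selectable via `variance: nei | none`. Sites with `N` in either member of a
pair are skipped pairwise-complete; `L` is **not** reduced (region lengths
are treated as fixed). Pooled estimates concatenate regions (pooled
differences over pooled length) rather than averaging per-region values;
per-region rows are also emitted.

## Cluster detection and the excess test

A cluster is a maximal chain of ≥2 variants assigned to the **same branch**
with every adjacent pair ≤ `max_gap` bp apart (default 50 bp). The span may
exceed `max_gap` (chaining is single-linkage). Homoplasic variants enter
once per (variant, branch) event, so a recurrent variant can sit in one
cluster per branch. Degenerate clusters (span 1 from coincident coordinates)
are flagged.

The null model randomizes `n` variant positions uniformly **without
replacement** over the `L` sequenced bases and assigns independent uniform
branch labels over the `B` branches; the statistic is the **number of
clustered variants** (not the number of clusters). The mean count λ over
1,000 replicates parameterizes a Poisson upper tail P(X ≥ observed),
evaluated by log-sum-exp over the pmf so magnitudes far below the
double-precision floor (~1e-308) remain exact in log10. If a finite
replicate set yields λ = 0 with a non-zero observation, λ is replaced by
1/(2·reps) and the result flagged (continuity guard). Sampling positions
with replacement, and a branch-margin-preserving null, are available as
switches.

Two calibration caveats, measured under the null itself:

- The clustered-variant count is **over-dispersed** relative to Poisson —
  every chance cluster contributes ≥2 variants, so the statistic lives on an
  even-dominated lattice. At α = 0.05 the Poisson tail is therefore mildly
  anti-conservative (empirical rejection ≈ 0.06–0.10 depending on n, L, B;
  ≈ 0.086 at the full-survey scale, where it equals P(≥2 chance pairs)).
  The regime the analysis operates in — tails of order 1e-20 against
  conventional α — is unaffected in any practical sense.
- The variant total carries a known bookkeeping ambiguity in the source
  data (134 variants in the results tables vs 136 in the analysis
  description); the default is 134 with `n_variants_override` available,
  and the choice is logged in the report metadata.

Fisher's exact test (two-sided, point-probability method, via
`scipy.stats.fisher_exact`) compares clustered proportions and homoplasy
fractions between datasets; published NGS-survey contingency counts are
shipped as fixed comparison inputs in `ltrconv.published`.

## Donor inference and tract bounds

Only clusters with span ≥ 3 bp enter the donor search (a 2 bp derived state
matches some paralog too easily). The cluster's **derived tract** is the
acceptor reference over the span with derived alleles substituted at member
positions; a library sequence is a donor only if its aligned bases over the
span are **100 % identical** to that tract — a single mismatch destroys the
hit, and multiple identical donors are all reported. Donors are expected
pre-aligned (equal length or with a declared offset); a deliberately simple
ungapped sliding exact-matcher is included for equal-scale paralogs, and
gapped alignment is out of scope. Genome-scale donor discovery (BLAT-like
search) is replaced by a user-supplied donor library: the identity criterion
is exact matching either way, and this keeps the package self-contained.

Tract bounds: the **minimum** tract is the cluster span itself (the bases
demonstrably converted). The **maximum** is limited by the nearest PSV on
each side at which the converted chromosome retains the *acceptor* base —
conversion cannot have crossed a site it failed to convert. With flanking
non-converted PSVs at positions L and R, the default (`between`) counts
`R − L − 1` bases strictly between them; `inclusive` (`R − L + 1`) is a
switch, since printed data cannot distinguish the two conventions. If a side
has no retained PSV inside the locus the maximum is undefined (`N.A.`).
Conversion classes: `intra-LTR` (donor interval inside the acceptor element
itself), else `Y-to-Y`, `X-to-Y`, or `autosome-to-Y` by donor chromosome.

The published cluster table encoded in `ltrconv.published` contains two
internally inconsistent rows, both handled as documented exceptions rather
than silently corrected: cluster 14 prints span 63 where its coordinates
give 64 inclusive, and cluster 12 prints a degenerate start = end coordinate
pair alongside span 2.

## The synthetic generator

`simulate_dataset` emulates the study regime: a random ancestral locus
(default 1550 bp — the size of the hotter of the two re-sequenced elements)
evolves down a fixed rooted tree (default a labeled 16-tip caterpillar, the
30-branch scale of the survey tree; any Newick may be supplied). Per branch:
Poisson(`mut_rate`, default 1.0) point mutations at uniform positions and
Poisson(`conv_rate`, default 0.3) conversions with uniform start, geometric
tract length (mean `tract_mean`, default 100 bp ≈ the observed mean tract,
truncated at the locus end) and a donor drawn uniformly from the library.
Donors differ from the ancestor at Binomial(L, `psv_rate`) positions
(default 2 %, the middle of the 1–3 % paralog-divergence range); conversion
overwrites the tract with the donor's bases verbatim. Donor evolution is not
simulated — truth stays unambiguous. An optional per-base `error_rate`
(default 0: Sanger-grade data) perturbs the tips.

To keep every segregating site biallelic (the analysis rejects
multi-allelic sites), each position carries one pre-drawn alternate base:
point mutations toggle ancestral ↔ alternate (yielding natural back
mutations), and donor PSVs use the same alternate base. This sacrifices
triallelic recurrences, which the real analysis would discard anyway.

Every event is logged (`SimTruth`) with branch, tract, donor and PSVs
covered. `truth_report` scores detection: recall over conversions covering
≥ `min_psvs` PSVs (others are undetectable in principle), precision over
detected clusters with ≥ `min_psvs` members — pair clusters arise from
chance mutations at exactly the rate the permutation null quantifies, so
they are scored by the excess test, not against the simulator. At the
default conditions, recall and precision average ≈ 0.94 over 100 seeds.

What the simulator does **not** emulate: donor-lineage mutation during the
tree (real donors drift, so old conversions can show <100 % identity),
alignment error, indel conversion, GC-biased repair, and site-specific
mutation-rate variation. Passing recovery tests therefore demonstrate the
machinery is correct under the stated generative model, not that real-data
sensitivity reaches the same numbers.

## Problem sizes and determinism

Defaults everywhere reproduce the declared analysis parameters: 50 bp gap,
1,000 permutation replicates, span ≥ 3 bp for donor search. The test suite
and the acceptance script run the permutation null at the full survey scale
(134 × 61,165 × 30) and simulator recovery over 100 replicate seeds —
seconds of compute — with all randomness derived from explicit seeds;
identical configurations give byte-identical outputs, including report
files. Raw p values are reported with no multiple-testing correction (a
handful of planned tests), and this is stated in the report metadata.
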