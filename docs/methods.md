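# Methods

## Data model and coordinates

A contig is a padded multiple alignment: reads in contig orientation
over `{A,C,G,T,N,*}` with `*` the assembler pad, each base carrying a
phred-like quality. ACE `AF` positions (1-based) become 0-based
`start_col`; all internal arithmetic is 0-based half-open, while report
tables use 1-based positions in *cleaned-column* space with a
provenance map (`kept_cols`) back to original padded columns. Pads have
no quality of their own in ACE/QUAL; a pad is imputed the **minimum of
its nearest non-pad neighbours** (one-sided at read ends). This is
deliberately conservative — a pad is never more trusted than its
context — and is one of the genuinely open choices here, since
assembler pipelines do not standardise pad qualities. `N` bases are
always masked: they never support a variant or the consensus. Organ
tags come from a `read_id → organ` sidecar because MID detection
happens on raw reads, upstream of the artifact this package consumes;
reads missing from the sidecar are `untagged`. Reads protruding past
contig bounds are clipped, with the clipped unpadded base counts
recorded so the QUAL vector can be sliced consistently; QA clipping
records are parsed but not applied.

## Masking and cleaning

Per column, three rules run **in order, in a single pass**, each seeing
the column as the previous rule left it:

1. **singleton** — variant states (≠ column majority) supported by one
   read;
2. **low_freq** — variant states at frequency < 0.1 among the column's
   still-unmasked non-N bases (denominator includes the variant
   itself);
3. **low_qual** — at columns still polymorphic (≥ 2 unmasked states,
   pads counting as a state), any individual base with quality < 20.

Majority ties break toward the earlier state in the fixed order
`A < C < G < T < *`, making the reference/variant split deterministic.
The rules are **not** iterated to a fixpoint: rule 3 can, in rare
columns, demote a surviving variant to singleton status that only a
second pass would re-mask. Iterating would cascade masks beyond what
the three stated criteria describe, so the implementation (and its
property tests) guarantee determinism and monotone re-application
rather than strict idempotence. Frequency masking applies to gap
variants exactly as to substitutions.

Cleaning deletes every column whose unmasked content is pads only —
the signature of 454 homopolymer over-calls, which would otherwise
corrupt the consensus and any primer design on it. The consensus is
then edited per kept column as the IUPAC code of the unmasked real
states at frequency ≥ 0.1 (among unmasked real bases); it is
lowercased when unmasked pads outnumber real bases (flagging a likely
deletion) and `N` when no real base qualifies.

## Mismatch calling and the binomial filter

Every kept column with ≥ 2 distinct unmasked states yields a record
with per-state counts and mean qualities, unmasked depth x, minor count
t, maf = t/x, and a class: > 2 states → multiallelic; a pad among two
states → indel; else transition (A↔G, C↔T) or transversion. Ti/Tv is
tallied over biallelic substitutions only; for multiallelic sites t is
the rarest state's count.

Three post-filters set flags without deleting records:

- **adjacent**: every member of a run of records at consecutive cleaned
  positions (adjacent mismatches are characteristic assembly
  artefacts; with no principled way to prefer one member, all are
  flagged);
- **binom_fail**: with 2N pooled gametes (2N = 2 × genotypes, default
  4), a true variant's expected pool frequency is ≥ p = 1/2N, so
  P(X ≤ t | x, p) < α (default 0.05) marks a likely false positive.
  The cumulative probability is the filter criterion; the point
  probability is also exposed because the minimal 2-of-8 configuration
  is naturally quoted as its point value (0.31);
- **low_depth**: x < 8.

`scipy.stats.binom` provides pmf/cdf; the test suite verifies the cdf
against exact rational summation to < 1e-12 absolute for all t ≤ x ≤ 60.

The density summary reports mismatches per 100 bp with the denominator
restricted to cleaned columns of unmasked depth ≥ 8, in two blocks that
differ exactly by the binomial test: *before* keeps records free of the
adjacency and depth flags, *after* additionally requires the binomial
pass. Both blocks share the denominator, so the filter can only lower
the density. Ti/Tv with zero transversions is reported `NA`.

## Contaminant screen and annotation

From a per-contig BLASTX hit table (with subject species/genus and
e-value) and a genus → green-plant lookup: a contig is *clean* when at
least one of its k = 10 lowest-e-value hits under e ≤ 1e-25 is
green-plant, *contaminant* when informative hits exist but none of the
top-k is, and *no_informative_hit* otherwise (kept but unannotated).
A genus missing from the lookup is an error, never a silent "not a
plant". Annotation takes the lowest-e-value informative green-plant
description, where "informative" is a configurable blacklist (default:
unknown / hypothetical / predicted protein / unnamed) — a necessarily
heuristic stand-in for the manual curation such screens often get; the
screen here is fully automated.

## GO-term permutation screen

Read counts per contig and organ proxy expression level. Per term and
organ, the observed statistic is the mean count over the term's contigs
excluding zero counts; the organ's count vector is permuted over **all**
contigs (zeros in the pool, exclusion re-applied after assignment —
a `pool="nonzero"` variant is available), default 1000 times, and the
term is flagged when the observed mean exceeds > 95% of permuted means.
The test is one-sided (over-expression; under-expression shows as a
negative mean permutation difference, reported descriptively) and
uncorrected by default, matching common practice for this screen; a
Benjamini–Hochberg option exists. A term whose permuted sample is all
zeros contributes a permuted mean of 0. All terms share one permutation
stream: results are bit-reproducible given the seed, but term results
are not independent — the null calibration test accounts for this only
through the generous 99% binomial interval it checks against.

## RaBoT

The empirical contig count of the smaller library is compared with
counts from n_boot = 100 subsamples of the larger library, drawn
without replacement at exactly the smaller library's read count; the
P-value is the fraction of bootstrapped counts **strictly above** the
empirical value (ties are not above, so identical libraries give P = 0).
Counts come from the fixed assembly's read → contig map rather than
per-bootstrap reassembly; this equals the rarefaction statistic
whenever assembly membership is stable under subsampling, and avoids
coupling the test to any particular assembler.

## Simulator

`simulate_assembly` emulates pooled-diploid 454 sequencing and plays
the assembler's role, emitting a consistent padded alignment plus a
complete `TruthSet`:

- contig lengths ~ Normal(460, 60) bp (min 150), matching typical
  454 transcriptome contigs; reads ~ Normal(220, 50) bp;
- reads per contig ~ negative binomial with mean 6.5 and shape 1.3 —
  low average coverage with a long right tail, so deep (≥ 8×) islands
  exist without being the rule; read placement guarantees every
  reference position is covered (contigs, by construction, have no
  coverage gaps);
- organ proportions (leaf, stem, root, untagged) = (0.30, 0.20, 0.48,
  0.02): root-heavy with a small untagged fraction, as organ-pooled
  plant libraries typically are;
- pool variants planted per base at rate 0.004, at gamete counts
  k ∈ {1..2N−1} (frequency k/2N, 2N = 4 by default); planted variants
  are kept non-adjacent so true variants never trip the adjacency
  filter among themselves;
- substitution errors at 0.5% per base, independent of quality;
  qualities ~ Normal(30, 5) with an 8-point mean decay toward the 3'
  read end, clipped to [1, 40];
- homopolymer over/under-calls per read and run (length ≥ 2), with
  probability growing in run length. Each over-call becomes its own
  mostly-pad column; under-calls become pads in the erring read.
  Events are planted **only where coverage lets the artifact surface
  as a removable pad column** (insertions need ≥ 3 spanning reads,
  deletions must leave retaining reads in strict majority): with a
  single covering read an assembler emits no pad column at all — the
  error silently enters the consensus — so such events are not
  observable in the artifact this package consumes and simulating them
  would assert an impossible recovery.

What the simulator does **not** emulate: flowgram-level 454 noise,
quality-correlated substitution errors, chimeric/misassembled contigs
(beyond what the filters are tested on directly), paralog collapse,
and insertion co-alignment (two reads over-calling the same run get
separate columns, where an assembler might merge them). Passing tests
therefore demonstrate the pipeline's logic and bookkeeping under
realistic magnitudes, not its error rates on real 454 data — the
published per-species counts and densities depend on the raw reads and
the upstream assembler and are not reproducible from synthetic data.

`simulate_go_table` draws per-contig rates Gamma(1.5, 1.5) (mean 2.25
reads/contig/organ) and Poisson counts, with random term memberships of
5–50 contigs; planted terms multiply their members' rate in one organ.
Because rates are shared across organs, a term holding intrinsically
high-expression contigs is legitimately elevated in every organ.

## Numerical and degenerate-input choices

- Binomial arguments validated (0 ≤ t ≤ x, 0 < p < 1); P(0 of 0) = 1.
- Empty density denominator → density `NA`; zero transversions → Ti/Tv
  `NA`; a GO term with no expressed contig → observed mean `NA`, never
  significant.
- All randomness flows through `numpy.random.default_rng(seed)`;
  simulation output and pipeline reports are byte-identical across
  reruns with the same seed.
- Report tables are TSV with `.` decimals and deterministic row order
  (contig, then position).

## Problem sizes used in the test suite

The property suites run on 1000 random 20-column alignments (masking
oracle), a 100-contig simulated assembly (truth recovery and summary
consistency), a 200-term × 1000-contig null table at 1000 permutations
(type-I calibration), and exact-rational binomial checks to x = 60 —
sizes chosen so the full suite exercises every claim in minutes on a
single core.
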