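# Methods

## Model and assumptions

`pyrodenoise` treats denoising as a per-sequence validation problem.  A
unique trimmed sequence is accepted as real only when its abundance
pattern is inconsistent with having been generated as an error of a more
abundant co-occurring sequence.  Three deterministic assumptions about
errors drive every decision: errors co-occur with their parents across
samples; errors have fewer reads than their parents; and each error type
(substitution, homopolymer indel, chimera) has a predictable abundance
relative to its parent.  There is no probabilistic model and no single
denoising step — a sequence must survive the filtering stage, the
cross-sample preliminary rules, the within-sample error-type tests, and
the replication-design threshold.

The conservative corollary is accepted as a design position: a sequence
observed exactly once in the whole dataset can never be validated, so real
singletons are missed by construction (deeper sequencing, not looser
thresholds, is the intended remedy).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `freq_cutoff` | 0.50 | minimum per-sample frequency relative to the group's top sequence at which a co-occurring sequence counts as independent |
| `rare_dataset_bound` | 10 reads | below this dataset abundance a sequence is "rare" and subject to the floors |
| `rare_min_reads_ms` | 3 reads | rare-sequence dataset floor, multi-sample mode |
| `rare_min_reads_ss` | 2 reads | rare-sequence dataset floor, single-sample mode |
| `sub_x` | 0.02 | substitution threshold base: a variant with *n* mismatches from a parent with *a* in-sample reads is invalid below *a·xⁿ* reads |
| `chi_y` | 0.15 | chimera threshold base: a daughter with *s* switches is invalid below *b·yˢ* reads, *b* = less abundant parent |

All thresholds are compared with strict "fewer than" and never rounded.
The rare-sequence floors are applied uniformly to top and additional group
members, so every validated sequence obeys the same minimum-read
requirements — this is what makes the detection floor exact.

`ReplicationDesign` holds the final-validation rule: `min_valid_obs` valid
per-sample observations (default 1), or, when samples are partitioned into
replicate blocks, a valid observation in every sample of at least one
block.  Ambiguous observations (single reads in a sample) never count as
valid, and invalid observations are not vetoes: a sequence valid in four
replicates and invalid in a fifth passes a 4-of-5 design.

`detection_floor` returns `(2·r, 2)` clamped below by the rare floor,
where `r` is the number of samples that must simultaneously hold valid
observations (`min_valid_obs`, or the smallest block).

## Alignment choices

Every error-type test is defined on alignments, so the aligner must be
bit-reproducible.  Pairwise alignments use `Bio.Align.PairwiseAligner` in
global mode with match +1, mismatch −1 and linear gap −1; the first
optimal traceback is deterministic for a fixed Biopython version.  A
reward-based global alignment is used deliberately instead of a
minimum-edit scheme with free end gaps: with free ends and zero match
reward, unrelated sequences admit zero-cost staggered alignments with no
internal differences, which would misclassify unrelated pairs as
"indel-only" relatives.  Global alignment forces full overlap, so
unrelated pairs show many substitutions and fail every pair test, which is
the intended behaviour.

Terminal-gap columns — columns inside any sequence's leading or trailing
gap run — are excluded from substitution counts and from pairwise
distances, so reads that terminated early are compared only over the
region they cover.  A pair whose only differences are terminal gaps (a
truncated read against its full-length parent) is classified indel-only,
the conservative reading for pyrosequencing truncation artifacts.

Three-way alignments align the two parents pairwise and then align the
daughter against the resulting two-row profile with an internal
Needleman–Wunsch (numba-compiled): a daughter base costs 0 in a column
where it equals either parent's symbol and 1 otherwise, gaps cost 1, and
ties are broken diagonal > gap-in-daughter > insertion.  In the chimera
scan a daughter gap aligned to exactly one parent's gap is informative for
that parent; a column where the daughter matches neither parent disquali-
fies the chimera hypothesis outright.  The switch count ignores columns
matching both parents, which equals the minimum number of parent-label
transitions over all consistent assignments (verified against exhaustive
enumeration in the tests).

Secondary validation evaluates the indel and substitution tests on all
pairs within the ranked-above set (these tests depend only on the pair, so
pair-level evaluation is equivalent to enumerating triples) and the
chimera test on full parent-pair triples, processed in descending combined
abundance with early exit once a daughter is flagged.  A triple is skipped
when the daughter's reads are at least *b·y*, the largest threshold any
switch count could produce; this prunes most triples without changing any
outcome.  Flagged sequences remain available as parents for later tests,
since their reads exist in the sample regardless of their own status.

## Grouping

Best-hit grouping consumes an externally produced sequence→accession
table; the package never performs database searches, and recorded hit
scores are ignored (group identity, not hit quality, is what matters).
The internal alternative is greedy abundance-sorted single-linkage
preclustering at radius 0.02: by default each sequence joins the first
group whose *seed* is within the radius (seed linkage), with transitive
single linkage behind a flag.  Ties in abundance are always broken
lexicographically by sequence, making every stage order-independent.

## The synthetic positive control

The generator emulates a replicated mock-community experiment: 16 clones
of 150 bp in three dilution groups — eight at relative concentration 1.0,
six at 0.1, and a pair of clones two substitutions apart at 0.05 each
(half the middle group, emulating the two alleles of one heterozygous
individual) — amplified in five replicate PCRs of 2000 reads, each
replicate carrying its own MID pair.  Default injected error rates are
10⁻³ substitutions per base per read, 10⁻³ indels per homopolymer run
(length ≥2) per read, and 10⁻² chimeras per read (single uniform interior
breakpoint, parents drawn proportional to concentration).  These rates are
realistic for 35-cycle PCR plus 454-style pyrosequencing and place
expected per-variant abundances far below the default thresholds: an
abundant clone contributes ≈1000 dataset reads, so a specific single-base
variant expects ≈1000·0.001/3 ≈ 0.33 reads per replicate — far below both
the 0.50 co-occurrence cutoff (≈100 reads) and the a·x substitution
threshold (≈4 reads per sample).  Errors are injected per final read, not
per PCR cycle: cycle-accurate lineage simulation would change nothing the
thresholds can see.

Deliberate stress inputs are available: `with_spiked_substitution` mixes a
single-substitution variant of a chosen clone at a clone-like
concentration (above the thresholds in every replicate), which the
pipeline — correctly, given its assumptions — validates as a false
positive; `extra_reads` injects exact low-count reads, e.g. a one-read
clone demonstrating the singleton limitation.

What the generator does *not* emulate: flowgram-level noise, quality
strings, per-cycle PCR lineages, position-dependent error hotspots,
chimeras with more than one breakpoint, and the long rare-taxon tail of
real environmental communities.  Passing tests on this mock therefore
demonstrate that the decision rules behave as specified under their own
assumptions, not that those assumptions hold for any particular platform
or community.

## Problem sizes and numerical notes

The reference mock (10⁴ reads, ≈1500 unique sequences, ≈200 after
filtering) runs through the full pipeline in a few seconds on one CPU;
tests use this scale or smaller.  Alignment results are memoised per
sequence pair/triple, which is what keeps the per-sample tests cheap
across five replicates sharing most sequences.  Degenerate inputs are
handled explicitly: empty read sets produce empty tables and an empty
ledger; duplicate sequence rows in one sample are a contract violation;
groups whose top sequence fails the top rules promote the next-ranked
member rather than discarding the group.

## Known limitations

- Real global singletons are never recovered (by design).
- Exact primer/MID matching discards reads with any error in the flanking
  sequence; there is no fuzzy matching, so accepted-read counts understate
  template abundance at high flank error rates.
- The substitution and chimera thresholds assume error abundance scales
  with parent abundance within a sample; systematic co-amplified variants
  above those thresholds (e.g. true intragenomic paralogs — or the spiked
  control) are accepted, which is the intended trade-off.
- Long amplicons whose reads rarely reach the reverse primer must use
  truncation mode, sacrificing the 3′ region and reverse-MID
  demultiplexing resolution.
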