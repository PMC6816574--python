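# Methods

## The error-correction model

`mrdseq` targets the regime where the variants of interest (0.001%–1%
VAF) sit below the raw per-base error rate of short-read sequencing
(~0.1–1%). The correction exploits the molecular structure of a
UMI-tagged capture library: every read descending from one original DNA
fragment shares that fragment's alignment coordinates and its 6-bp UMI,
while errors introduced during PCR or sequencing are (mostly)
independent across reads.

**Family grouping.** Reads are partitioned by the exact key
(contig, aligned start, aligned end, UMI). Two distinct molecules
collide only if they share both endpoints and a UMI (probability
~4⁻⁶ per coordinate-sharing pair), which is negligible at panel scale.
By default UMIs must match exactly; an optional tolerance-1 mode merges
coordinate-identical families whose UMIs differ by one substitution
(larger family absorbs smaller, ties broken lexicographically by UMI).
Exact matching is the default because it is the simpler, more
conservative reading of the grouping rule; tolerance merging mainly
recovers families fragmented by UMI sequencing errors. Reads without a
UMI tag are diverted to a counted side channel, never silently dropped.

**Consensus.** Families with fewer than `min_family_size` (default 3)
reads are discarded — two reads cannot outvote each other. For
qualifying families, each reference position is called by strict
majority: the base must be carried by **more than** `majority_fraction`
(default 0.5) of the members holding a real base there. Member N bases
and members whose deletion spans the column leave the denominator.
With no strict majority the consensus is N; N positions are excluded
from every downstream depth denominator and from variant calling.
Plurality would never produce N in a size-3 family, so strictness is
essential to the model. Indel events are called only when the
*identical* event (same coordinates and allele) is carried by a strict
majority of the family; partially overlapping events never merge.

For a size-3 family with per-base substitution error rate *e*, a wrong
consensus base requires ≥2 concordant errors. Exact enumeration over
all 4³ member-base combinations gives

P(consensus = specific alt) = 3(*e*/3)²(1 − *e*/3) + (*e*/3)³,

about 8×10⁻⁶ per alternate base at *e* = 0.005. The test suite checks
the simulated pipeline against this enumeration (not the algebraic
approximation) within 3 Monte-Carlo standard errors.

**Quantification.** A tracked variant's VAF is alt-supporting consensus
reads over the N-excluded consensus depth at the locus. Insertions are
keyed by their exact inserted sequence at the anchor base and use the
anchor column's depth as denominator (the mpileup-compatible choice);
deletions are keyed by their exact deleted interval and tallied at the
VCF anchor. Reads whose called deletion spans a column count toward
that column's spanning total but toward no base. Internal coordinates
are 0-based half-open everywhere; VCF and TSV interfaces convert at the
boundary, and indels are left-normalized against the reference so that
simulator truth and caller output are comparable.

**Calling.** Detection thresholds are ≥0.1% VAF for point mutations
and ≥0.001% VAF for indels ("at or above": the comparison is `>=`).
The indel cutoff lies below one read at routine 10,000–20,000×
collapsed depths, so a `min_alt_reads` parameter (default 1) makes the
effective indel rule explicit. Variants whose control-cohort noise
reaches 0.1% are blacklisted before calling; the default rule excludes
a variant when its mean control VAF is at/above the cutoff **or** when
two or more individual controls reach it ("recurrent" noise), with both
halves available separately because the original exclusion outcome is
documented but the exact statistic is not. A sample whose retained
variants are all blacklisted or all uncovered is reported
`Untrackable`, never `Negative`.

## Cohort statistics

The patient-level association between MRD positivity and relapse is
tested with the two-sided Fisher exact test (sum of hypergeometric
probabilities of all margin-preserving tables no more probable than the
observed one; delegated to `scipy.stats.fisher_exact`, with an
exhaustive enumeration oracle in the tests). The packaged relapse
cohort (30 patients positive 18/12, 9 non-recurrence patients positive
0/9) gives the table [[18, 12], [0, 9]] and p = 0.0016; the table
construction is a documented derivation, since only the p-value is
conventionally reported. Group VAF differences use the Mann–Whitney U
with midranks and the tie-corrected normal approximation without
continuity correction (U reported as the smaller one-sided statistic;
a z-score is exposed because that is how such results are reported).
Days-before-relapse bins are closed intervals 21–40, 41–60, 61–80,
81–100; the patient-positivity window is 20–100 days inclusive.
Date-matched BM/PB pairs are counted per patient.

## What the simulator emulates — and what it does not

`simlib` draws unique fragments uniformly over a territory (length
normal, default 300±60 bp; 6-bp UMIs uniform over {A,C,G,T}⁶), marks
spike-in carrier molecules by a Binomial(n, VAF) draw *independent of
fragment placement* (so the locus-level VAF estimator is unbiased even
when fragments only partially cover the locus), amplifies each molecule
into a zero-truncated negative-binomial number of reads (default mean
6, dispersion 2 — chosen so ~79% of families clear the 3-read filter,
mirroring >10,000× collapsed depth from >15M read pairs in practice),
and applies three substitution-error processes: lineage-shared PCR
errors on each of two first-cycle branches, independent per-read PCR
errors (both at `pcr_error_rate`, default 10⁻⁶/bp), and per-read
sequencing errors (`seq_error_rate`, default 0.5%/bp). An
`oxidation_bias` fraction of PCR errors is forced to C>A/G>T changes,
emulating oxidative DNA damage, the dominant source of recurrent
artifact noise. Reads are stored sparsely (coordinates plus differences
from the reference), which keeps 100-replicate experiments with ~250k
reads each inside a few minutes on one core.

Deliberate simplifications, and hence what passing tests do *not*
demonstrate about real data:

- Mates are merged: a read models a whole fragment, because consensus
  keys on fragment endpoints, not mate structure. Soft-clipping and
  mapping ambiguity do not exist here.
- Alignment is perfect — reads carry truth coordinates — and there is
  no re-alignment after consensus merging. Alignment-induced artifacts
  (especially around ITD-like insertions at intron/exon boundaries) are
  out of scope; tracked insertions match by exact sequence only.
- Error processes are substitution-only; polymerase slippage indels are
  not simulated, so the observed absence of indel noise in simulated
  controls is structural (it mirrors, but does not independently
  re-demonstrate, the near-absence of indel artifacts in real data).
- Base qualities are constant; there is no quality-weighted voting.
- A full PCR branching process is reduced to a two-generation scheme;
  this creates within-family error correlation (which consensus must
  tolerate) without simulating six cycles of lineage topology.

## Numerical and design choices

- Majority is strict (`count > fraction × covering`), so a 2/4 split is
  N, and exact half never calls. Ties among alternate bases at equal
  counts resolve to the lexicographically smallest base; this can only
  matter when no strict majority exists, i.e. the call is N anyway.
- Collapse has two code paths — a dense per-family vote (the reference
  implementation) and a vectorised sparse path over read-difference
  arrays — verified equivalent property-by-property in the tests.
- Zero-depth positions are *missing* in error profiles and pileups,
  never zero; zero margins make Fisher's p exactly 1 by convention;
  identical groups give Mann–Whitney z = 0, p = 1.
- Degenerate family-size parameters fall back to size-1 families with a
  warning; empty inputs produce empty outputs with zeroed QC metrics.
- Seeds: every stochastic operation derives its generator from the
  `SimConfig` seed; identical configs are bit-reproducible.

## Validation problem sizes

The validation experiments run at desk scale, chosen once: the
limit-of-detection experiment uses 100 replicates of 40,000 molecules
over a 2 kb territory with fragment length 820±80 bp, giving ~22,000×
collapsed depth at the spiked locus (the depth regime of the assay at
reduced territory); specificity uses 20 no-spike control samples at
~6,000× depth, where a single consensus error (~10⁻⁶/base) sits far
below the 0.1% cutoff; consensus-error calibration uses ~10⁶ consensus
calls per error rate. Detection of a spike at *exactly* the detection
threshold is intrinsically a coin flip (the estimator is unbiased, so
half of replicates fall below the cutoff); the experiments therefore
check the detection *fraction* against a binomial oracle and the
estimate's unbiasedness within 3 standard errors, rather than asserting
near-certain detection at the limit.

## Known limitations

- No duplex (two-strand) consensus: errors on the first PCR cycle that
  dominate one lineage can survive single-strand consensus.
- No de novo variant discovery: only pre-designated variants are
  quantified.
- Exact-sequence insertion matching undercounts ITDs whose reads align
  ambiguously.
- The blacklist rule operationalizes a documented outcome (recurrent
  ≥0.1% control noise) whose original statistic was not specified; both
  supported rules are configurable.
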