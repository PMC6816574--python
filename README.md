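# mrdseq

Error-corrected UMI consensus analysis for tracking measurable residual
disease (MRD) with hybrid-capture NGS panels.

After hematopoietic cell transplantation, AML patients are fully
engrafted with donor blood cells, so *any* recurrence of a
patient-specific somatic mutation — even in genes associated with clonal
hematopoiesis — signals relapse. Detecting such mutations months before
morphological relapse requires calling variants at 0.1% VAF and below,
far beneath the raw error rate of standard sequencing. `mrdseq`
implements the informatics that makes this possible, together with a
synthetic-data generator that lets every stage be validated against
known molecular truth:

- **UMI family consensus.** Aligned reads are grouped by fragment
  start/end plus a 6-bp unique molecular identifier, each group ideally
  representing one original DNA molecule. Families with ≥3 reads are
  reduced to a consensus by per-position strict-majority vote; a
  position with no majority is called **N** and excluded from all
  downstream depth statistics and variant calling. For a size-3 family
  with per-base error rate *e*, the residual error rate falls from *e*
  to roughly 3(*e*/3)²(1−*e*) per alternate base — two orders of
  magnitude at *e* = 0.5%.
- **Pileup quantification.** Per-position allele counts over consensus
  reads; a tracked variant's VAF is alt-supporting consensus reads over
  the N-excluded consensus depth at the locus.
- **Noise blacklisting.** Each trackable variant's false-positive noise
  is profiled across control samples; variants with artifactual noise at
  or above 0.1% VAF (typically C>A/G>T oxidation damage) are excluded.
- **Dual-threshold MRD calls.** A sample is MRD-positive if any retained
  patient variant is seen at ≥0.1% VAF (point mutations) or ≥0.001% VAF
  (indels, which are nearly free of polymerase error).
- **Cohort statistics.** Pre-relapse detection rates binned by
  days-before-relapse, patient-level positivity, bone-marrow vs
  peripheral-blood comparison, Fisher's exact test on the patient-level
  relapse × MRD table, and a tie-corrected Mann–Whitney U. The clinical
  sample table of the validation cohort (30 relapsing patients, 56
  specimens) ships as a fixture.
- **Simulator.** Unique molecules over a target territory, spike-in
  variant molecules at a configured VAF, PCR duplication with
  lineage-shared polymerase errors (optionally biased to C>A/G>T
  oxidation artifacts), and per-base sequencing error — all with exact
  per-molecule truth reporting.

## Worked example

```python
import numpy as np
from mrdseq import (Reference, SimConfig, GenomicInterval, TrackableVariant,
                    simulate_sample, collapse_sample, summarize_variant,
                    Thresholds, call_mrd)

rng = np.random.default_rng(123)
reference = Reference.from_sequences({"chr1": "".join(rng.choice(list("ACGT"), 2000))})
base = reference.base("chr1", 1000)
spike = TrackableVariant(chrom="chr1", pos=1000, ref=base,
                         alt="T" if base != "T" else "C", label="NPM1_marker")

config = SimConfig(n_molecules=40_000, region=GenomicInterval("chr1", 0, 2000),
                   seed=7, fragment_length_mean=820, fragment_length_sd=80,
                   spikes=[(spike, 0.002)], seq_error_rate=0.005)
molecules, reads, truth = simulate_sample(config, reference)
consensus, metrics = collapse_sample(reads)
obs = summarize_variant(consensus, spike)
result = call_mrd([obs], [spike], Thresholds())

print(f"raw reads: {metrics.raw_read_count}, consensus reads: {metrics.consensus_count}")
print(f"collapsed depth at locus: {obs.depth}")
print(f"true VAF: {truth.spikes[0].true_vaf:.4%}, estimated VAF: {obs.vaf:.4%}")
print(f"MRD status: {result.status}")
```

prints

```
raw reads: 257298, consensus reads: 31586
collapsed depth at locus: 22224
true VAF: 0.1750%, estimated VAF: 0.1755%
MRD status: Positive
```

40,000 molecules were amplified into ~257k reads; collapsing UMI
families back to ~32k consensus reads removes the sequencing noise, the
0.2% spike is recovered within sampling error at 22,224× collapsed
depth, and the sample is called MRD-positive at the 0.1% cutoff.

The same pipeline is available from the shell:

```
mrdseq simulate --reference ref.fa --region chr1:1-2000 --n-molecules 40000 \
    --seed 7 --spike chr1:1001:A:T:0.002 --out-sam reads.sam --out-truth truth.tsv
mrdseq collapse --in-sam reads.sam --reference ref.fa \
    --out-sam consensus.sam --out-metrics metrics.tsv
mrdseq call --in-sam consensus.sam --reference ref.fa --variants tracked.tsv --out mrd.tsv
mrdseq report --fixture cohort
```

`mrdseq report --fixture cohort` summarizes the packaged clinical
cohort:

```
In-window samples (20-100 days): 46 (BM 28, PB 18)
Patient-level detection: 18/30 (60.0%)
BM detection: 15/28 (53.6%)
PB detection: 9/18 (50.0%)
Bin 21–40 days: 8/12 (66.7%)
Bin 41–60 days: 6/14 (42.9%)
Bin 61–80 days: 10/13 (76.9%)
Bin 81–100 days: 0/7 (0.0%)
Samples beyond 100 days: BM 7, PB 3
Date-matched BM/PB pairs: 8 (7 patients)
Fisher exact (patients, relapse x MRD): [[18,12],[0,9]] p = 0.0016
```

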