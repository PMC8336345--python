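# Methods

`cnvrassoc` implements a genome-wide CNV-region case-control analysis of
SNP-array intensity data: simulated cohorts of LogR-ratio (LRR) / B-allele-
frequency (BAF) tracks are segmented by three independent callers, filtered
by stringent sample- and call-level quality rules, intersected into
two-caller consensus calls and cross-sample CNV regions (CNVRs), and tested
for case-control association with burden, Fisher-exact, FDR, meta-analysis,
enrichment and expression stages.

## Signal model

Every component shares one emission model over copy states CN0..CN4.

**LRR.** Per marker, LRR ~ Normal(mu_s, sigma) with state means

| state | CN0 | CN1 | CN2 | CN3 | CN4 |
|-------|-----|-----|-----|-----|-----|
| mean  | −3.5 | −0.66 | 0 | +0.40 | +0.68 |

Diploid signal is centred at zero by construction; the non-diploid means
follow the convention shared by the established SNP-array callers (a
homozygous deletion is nearly signal-free, hence the large negative mean;
gains compress because intensity is log-scaled). sigma is either fixed
(`CallerParams.lrr_sd`) or estimated per sample as 1.4826 × MAD of the
track, floored at 0.02 — the robust estimate is insensitive to the CNV
segments themselves.

**BAF.** Within a copy state of CN total copies, the genotype carries k
copies of the B allele with binomial probability at the marker's population
B-allele frequency (PFB), and BAF is emitted at the allelic ratio k/CN
plus truncated-normal noise on [0,1]. Homozygous bands (k = 0 or CN) get a
quarter of the heterozygous-band noise scale, emulating the tail
compression of array chemistry. CN0 has no allelic signal and is uniform on
[0,1]. The caller-side BAF likelihood additionally mixes in a uniform
outlier component with weight 1e-4 so that a single off-model marker (a
genotyping artifact) cannot assign −inf to the true state and split a
segment.

**GC waves.** The simulator can add `amplitude × standardized local GC` to
every track; `gc_correct` removes the GC-linear component by ordinary least
squares (slope of LRR on standardized GC), preserving the track mean. The
operation is idempotent and exact on noiseless linear input.

## Synthetic cohorts

`build_snp_map` draws exponential inter-marker gaps (a memoryless stand-in
for real array spacing, whose true distribution is not modelled), a smooth
sinusoid-plus-noise GC profile squashed into [0,1], and PFB uniform on
(0.05, 0.95). `simulate_cohort` implants `CnvLocus` events: carriers are
drawn independently per sample at the phenotype-specific design frequency
(no diploid two-allele inheritance model — adequate for the
frequency-contrast statistics this package computes, not for segregation
analyses). Everything is driven by one `numpy` Generator seed; identical
arguments give bit-identical cohorts.

What the generator deliberately does **not** emulate: raw two-channel
intensities and genotype clustering, linkage between markers, mosaic
fractions, batch effects beyond the GC wave, and sex chromosomes. Passing
recovery tests therefore demonstrate that the pipeline's decision rules
behave correctly in the signal/noise regime the model describes, not that
any specific array product would achieve the same operating
characteristics.

## The three callers

The callers re-create the decision structure of the three detection
strategies commonly combined in array-CNV studies, on the shared emission
model, so that multi-caller consensus is meaningful:

* **hmm** — Viterbi decoding over CN0..CN4. Self-transition probability is
  distance-dependent, `1 − (1−p_stay)(1−exp(−d/D))` with defaults
  p_stay = 0.999 and D = 100 kb; the leaving mass is split over the other
  states proportionally to the state prior (0.99 diploid, 0.0025 per
  non-diploid state). Contiguous non-diploid same-state runs become calls;
  confidence is the log10 likelihood ratio of the called state against
  diploid summed over the segment. The decoder is verified against
  exhaustive enumeration of all 5^8 paths on small instances.
* **bayes** — the same decoding machinery applied after GC correction;
  confidence is MaxLogBF, the log10 Bayes factor of the best non-diploid
  state against diploid over the segment. Calls at MaxLogBF ≤ 10 are
  emitted but removed by call-level QC (the threshold is strict for this
  caller).
* **gaussian** — a partition scan: per marker, the log10 advantage of the
  best loss state (CN0/CN1) and best gain state (CN3/CN4) over diploid is
  computed, and all Ruzzo–Tompa maximal scoring segments with total
  advantage ≥ 35 become calls. Maximal-segment scanning (rather than runs
  of per-marker best states) is what lets one event absorb interior markers
  that individually classify diploid; at moderate noise, per-marker runs
  fragment 100-probe events into pieces. CN3/CN4 (and CN0/CN1) are pooled
  per type because their signal distributions are near neighbours and
  per-marker classification flips between them inside one event; the
  reported copy number is the pooled type's best-scoring state over the
  segment.

Confidence scores of all three callers live on one log10 scale, so the
conventional thresholds (10, >10, 35) are directly comparable.

## Quality control

Sample level (defaults; all strict "greater than" exclusions): the HMM
caller drops samples with SD(LRR) > 0.35, BAF drift > 0.01 (fraction of
markers with BAF in (0.2,0.25)∪(0.75,0.8)) or GC-wave factor > 0.05; the
Bayes caller drops SD(LRR) > 0.25, SD(BAF) > 0.3 (within the heterozygous
band) or outlier rate > 0.01 (fraction |LRR| > 1); both drop samples with
more than 50 calls. The Gaussian caller has no sample limits. In the
pipeline, a sample failing ≥ 2 callers leaves the cohort entirely (it can
never produce a two-caller consensus call); failing one caller removes only
that caller's calls.

Call level: keep n_probes ≥ 5 AND length ≥ 5000 bp AND confidence at
threshold (inclusive for hmm/gaussian, strict for bayes). Length is
end − start + 1 with 1-based inclusive coordinates. Calls overlapping an
exclusion-region union (telomeres, centromeres, immunoglobulin regions,
segmental duplications — supplied as BED) by ≥ 50% of their length are
removed. Neighbouring same-sample same-type calls merge when the gap is
strictly less than half their combined length, repeated to a fixpoint.

## Consensus and CNVRs

A consensus call requires the same copy type from ≥ 2 distinct callers with
reciprocal overlap ≥ 0.5 (of *both* intervals; the threshold is
configurable because the convention, not the value, is standard). Groups
are formed greedily by leftmost start (ties to the longest call), each raw
call supporting at most one consensus call; the consensus interval is the
common intersection.

CNVRs are built per chromosome and copy type by an innermost-boundary
sweep: consensus calls sorted by start accumulate while the running
intersection (max start, min end) is non-empty; when a call breaks the
intersection, the current intersection is emitted as a CNVR and the sweep
restarts with the breaking call plus any accumulated calls that still
overlap it. Every contributing call fully covers its CNVR, so CNVR
carriership is well defined, and same-type CNVRs on a chromosome are
pairwise disjoint. Loss and gain are tracked separately, so one locus can
yield two CNVRs. CNVRs carried by < 1% of the cohort are removed.

## Statistics

* **Association** — per CNVR, a two-tailed Fisher exact test on the
  (case carriers, cases without, control carriers, controls without)
  table, with the "probability mass ≤ observed (1+1e-7 slack)" tail rule;
  Benjamini–Hochberg FDR over all tested CNVRs. Delegated to
  scipy/statsmodels and verified against full hypergeometric enumeration.
* **Meta-analysis** — for genes shared between two cohorts' significant
  records, Fisher's combined probability: X = −2Σln p ~ χ² with 2k degrees
  of freedom, k the number of (cohort, copy-type) p-values combined.
* **Burden** — per-sample summaries (call count, any-call indicator,
  total kb, genes spanned, any-gene indicator, genes per kb) compared as
  case mean − control mean with a one-sided label-permutation p-value
  using the +1 correction, (1 + #{perm ≥ obs}) / (1 + n_perm); never zero,
  exactly uniform under the null in the absence of ties. Default
  n_perm = 10,000.
* **Pathway enrichment** — per sample, the fraction of its CNV-overlapped
  genes that belong to the pathway (samples overlapping no gene are
  excluded — their ratio is undefined — and the exclusion set is
  label-independent); group difference tested by label permutation. The
  within-sample normalization is what controls for gene and CNV size/rate
  differences.
* **Overrepresentation** — per annotation term, fold enrichment
  (q/Q)/(t/N) and a one-sided Fisher p in the direction of deviation, with
  Bonferroni over terms. Term databases are user-supplied GMT files; no
  external classification system is bundled, so published fold enrichments
  that depend on a versioned database are out of scope.
* **Expression percentiles** — per tissue, a gene's percentile is its
  mid-rank over all genes of the expression table
  (100 × (#smaller + ½#equal)/n); query genes above the 90th enter the
  high list, below the 10th the low list. Mid-ranking makes ties share a
  rank, so a constant column selects nothing (a strictly-smaller rule
  would dump every tied gene into the low tail). A PLIER-normalized
  ocular-tissue table for the glaucoma-associated genes ships with the
  package as a worked-example fixture.
* **Power** — χ² goodness-of-fit power at Cohen's w: noncentral
  χ²(df, λ = n·w²) upper tail beyond the central critical value.

## Evaluation conditions

The simulation studies in `cnvrassoc.experiments` use a compact map — one
chromosome, 1,200 markers at 3 kb mean spacing — with four 50-probe loci:
one deletion at 20% case vs 2% control carrier frequency and three
equal-frequency null loci (two deletions, one duplication), cohorts of
300 + 300 at LRR noise 0.2. These sizes keep a 50-seed, two-cohort study
within minutes on one CPU while preserving the per-event signal-to-noise
(~2.4 log10 per marker for a CN1 deletion at sd 0.2) and carrier-count
scale of the motivating study design. The recovery study asserts that the
contrast locus reaches BH-FDR < 0.05 in ≥ 90% of seeds in both cohorts,
that implanted loci are recovered as same-type CNVRs with ≥ 90%
sensitivity, and that null loci are nominally significant ≤ 8% of the
time. Null calibration draws 500 exchangeable replicates and checks the
burden p-values against uniformity with a Kolmogorov–Smirnov test on the
continuous total-kb metric (integer metrics have permutation ties, which
make the empirical p conservative rather than uniform).

## Numerical choices and degenerate inputs

* All coordinates are 1-based inclusive internally; BED files are 0-based
  half-open, converted only at the read/write boundary.
* Viterbi ties resolve to the lowest state index via argmax; continuous
  emissions make ties measure-zero.
* Chromosome boundaries get an infinite inter-marker distance (maximal
  transition reset) and calls never span chromosomes.
* The sd(LRR) floor of 0.02 keeps noise-free synthetic input decodable.
* Permutation comparisons use a 1e-12 slack so exact ties survive
  float summation-order noise.
* Empty inputs raise `ValueError` early (empty cohort, empty track,
  zero-size cohort in the frequency filter, empty pathway, empty
  reference).

## Known limitations

* Caller equivalence to the established external tools is structural, not
  numerical: their internal parameters are unpublished, so no attempt is
  made to match their outputs call-for-call.
* The simulator's independence assumptions (between markers beyond state
  persistence, between samples, between loci) understate the correlation
  structure of real arrays; operating characteristics measured here are
  upper bounds for messy data.
* FDR-adjusted p-values depend on the number of CNVRs tested, which in a
  real cohort is data-dependent; published adjusted values are therefore
  not reproducible from printed tables and are not asserted anywhere.
* The two-cohort meta-analysis matches cohorts by gene name only; no
  cross-cohort boundary harmonization is attempted.
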