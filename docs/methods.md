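# Methods

plasmakit interprets cell-free DNA (cfDNA) sequencing of metastatic
prostate cancer: it estimates the circulating-tumor-DNA fraction of a
plasma sample, calls microsatellite instability (MSI), classifies
somatic variants into clonal/subclonal and genes into wild-type /
monoallelic / biallelic states, and removes clonal-hematopoiesis (CH)
false positives using matched white-blood-cell (WBC) DNA. Because no
patient-level data ships with the package, a seeded synthetic-cohort
generator emulates the statistical structure the analysis assumes and
carries the ground truth every test is scored against.

## Mixture model

All quantitative reasoning rests on one mixture model. Writing `tf` for
the fraction of cfDNA molecules of tumor origin:

* a somatic variant on `m` of `CN_t` tumor copies has expected allele
  fraction `VAF = m·tf / (CN_t·tf + 2(1−tf))`;
* a segment at tumor copy number `CN` has expected coverage ratio
  `r = (CN·tf + 2(1−tf)) / 2` against a diploid control;
* its mirrored het-SNP B-allele fraction is
  `BAF = (M·tf + (1−tf)) / (CN·tf + 2(1−tf))` for major-allele copy
  number `M`.

`tf_from_mutation` inverts the first relation
(`tf = 2·VAF/(m + VAF(2−CN_t))`, clipped to [0,1]); `tf_from_cna`
inverts the other two per segment and takes the n_snps-weighted median
across aberrant segments, averaging the coverage and BAF routes where
both are informative. Per-segment estimates spreading more than 0.15 set
a discordance flag. The same algebra, read as clone cellularity instead
of tumor fraction, prices arm-level copy-number events in WBC DNA
(`cellularity_from_arm_event`).

### Combined estimate

The mutation-based estimate is the 90th percentile of per-variant
`tf_from_mutation` values over coding variants with ≥ 3 alt reads: an
upper robust summary that tracks the clonal peak while resisting
subclonal dilution. Multiplicity defaults to 1 and is promoted (one
refinement pass) only when a variant's VAF at the provisional estimate
implies m ≥ 2; variants presumed subclonal at the provisional estimate
(VAF < tf/4) are then dropped. Where the CNA profile suggests a higher
tumor burden the estimate is taken from the CNA profile:
`tf_final = max(tf_vaf, tf_cna)`.

The 90th percentile of a handful of noisy per-variant estimates is
biased upward by order statistics (≈ +1 read-depth standard error at
typical variant counts); combined with the max() rule this dominates the
estimator's error budget. At 800× and 4–10 informative variants per
sample the median absolute error over the simulated cohort is ≈ 0.02–
0.03, which is the regime the detection tiers need.

Detection tiers use fixed, inclusive cutoffs on `tf_final`: 0.02 (point
mutations), 0.10 (LOH), 0.20 (homozygous deletions). Inclusivity at the
boundary is a documented convention, tested explicitly.

CH variants masquerade as high-VAF somatic calls, so the intended
composition order is: CH filter first, then tumor-fraction estimation on
the CH-cleaned call set. The tests and the `report` command follow that
order.

## MSI calling

Scoring is baseline-referenced in the style of mSINGS. The per-locus
statistic is the number of supported repeat-length alleles: lengths with
read support ≥ `peak_fraction` (default 0.05) of the modal length's
support. A baseline over ≥ 2 normals records the mean and population SD
(divisor n) of that statistic per locus; a locus is unstable when its
statistic exceeds `mu + k·sigma` (default k = 2) at depth ≥ 30. The
sample score is the fraction of unstable loci among ≥ 30 evaluable loci,
and MSI is called at score ≥ 0.10 (inclusive). The parameters mirror the
published mSINGS defaults and are all exposed on `MsiCaller`, which
wears a scikit-learn jacket: `fit(normals)` builds `baseline_`,
`score_samples`/`predict` evaluate query samples.

Sample-level gating: samples below 0.1 ctDNA fraction are not evaluable
(too little tumor signal to shift histograms). A sample whose score
clears 0.10 without an accompanying increase in mutation count (total
SNVs+indels, including intronic and synonymous, above 3× a cohort
reference median) is downgraded to MSS when its copy-number burden
(fraction of genome in non-neutral segments) exceeds 0.3 — a
chromosomal-instability phenotype can distort microsatellite histograms
without mismatch-repair deficiency. Without that copy-number evidence
the sample stays MSI with a low-confidence flag; the downgrade is an
explicit, configurable rule rather than silent judgment.

`dilution_benchmark` mixes each MSI sample's locus histograms with a
normal's at read level (each read drawn from the tumor histogram with
probability `purity`), scores the mixtures, and reports sensitivity per
purity plus the purity-invariant specificity of undiluted stable
samples. Only the score-threshold rule is exercised; the mutation-count
cross-check needs variant calls and is bypassed by design.

## Variant interpretation

Truncating, frameshift, splice and hotspot mutations are high impact;
non-hotspot missense variants without pathogenicity annotation are VUS.
Structural variants spanning exons are high impact; those confined to a
single intron (or a promoter) are VUS. SV supporting fractions are
systematically under-recovered by split/discordant-read counting, so
they are rescaled by `median(mutation VAFs)/median(SV fractions)`
(capped at 1) before clonality assessment. Clonality: subclonal iff
allele fraction < tf/4 (strict), NA when tf = 0.

Biallelic inactivation: a homozygous deletion alone suffices; otherwise
a clonal high-impact event plus a second allele-inactivating event (LOH,
second clonal high-impact mutation, or disrupting SV). One clonal
high-impact event alone is monoallelic. Phasing is not observable in
this data, so two hits count as biallelic without proof they sit on
different alleles — a deliberate, documented limitation. LOH evidence is
taken from the upstream segmentation call (`deletion_LOH`/`neutral_LOH`)
or, as a fallback, from a deletion-consistent ratio with mirrored BAF ≥
0.65. A fixed BAF threshold alone would be wrong at moderate purity: for
one-copy loss the expected mirrored BAF is `1/(2−tf)`, which stays below
0.65 until tf = 0.5, while LOH is detectable from ~0.10 — hence the
call-aware rule. A homozygous deletion co-occurring with a clonal
mutation in the same gene is contradictory (no template remains) and
yields a conflict flag instead of a call. SV breakpoints persisting
inside a homozygous deletion set `residual_breakpoint`, a marker that
stays detectable at low tumor fraction. In MSI samples high-impact hits
are largely passengers; statuses are flagged and excluded from cohort
biallelic-rate summaries.

Amplification calls require focal coverage ratio ≥ 1.15, with a weak
tier at 1.05–1.15 recorded but not counted as allele-inactivating; the
exact weak-amplification boundary is exposed in configuration because no
principled value exists.

## Clonal-hematopoiesis filter

Fixed composition (each step narrows or relabels, never adds):
discovery in WBC against a pooled-healthy-donor background (one-sided
exact binomial test, α = 0.01, ≥ 3 alt reads; per-site background rates
with a global 2×10⁻³ fallback), germline exclusion (WBC allele ratio
> 25% outside known somatic hotspots), validation in patient-matched
cfDNA with the same test, then flagging in the somatic profile by
(chrom, pos, ref, alt) identity. The germline rule is idempotent and
hotspots are exempt regardless of allele ratio.

Power at WBC depth 445×: the critical alt count under the 2×10⁻³ null is
4–5 reads, so detection is essentially certain at WBC VAF ≥ 0.05 and
≈ 95–98% at VAF 0.02. Exactly zero missed CH events can therefore only
be promised in the ≥ 0.05 regime, which is what the end-to-end tests
plant. Conversely, a passenger can be falsely flagged only when
sequencing errors produce a boundary-significant WBC count; at the
default error model this is a ≲ 10⁻⁴-per-variant event, visible roughly
once per ~10 cohorts of 100 patients.

Arm-level WBC copy-number expansions (≥ 30 Mb) are reported with the
cellularity implied by both the coverage ratio and the SNP allele ratio
and their agreement gap; shorter events are reported as focal.

## Synthetic cohort

Defaults encode the study conditions: 800× cfDNA and 445× WBC mean
depths with per-target log-normal spread (σ = 0.25, mimicking capture
non-uniformity), 100 microsatellite loci, 10% unstable loci in MSI
samples, tumor fraction uniform on [0.05, 0.8] unless pinned,
read counts binomial with optional beta-binomial overdispersion, segment
ratios with multiplicative log-normal noise (σ = 0.02, reflecting the
many-bin averaging of segment-level ratios), BAF noise σ = 0.01,
background sequencing error 5×10⁻⁴ per base.

Tumor-suppressor states are planted per gene (wild-type 50%,
monoallelic 15%, biallelic 35%) with an explicit mechanism — homozygous
deletion, mutation+LOH, two mutations, or mutation+SV; homozygous
deletions retain a residual breakpoint junction with probability 0.3.
CH variants appear in both compartments at matched allele fractions
drawn log-uniformly from 0.005–0.5 (hotspot flag on 40%); germline-like
variants sit at ~50% in both. The emitted somatic call set applies the
matched-WBC germline subtraction (≥ 3 cfDNA alt reads, not
germline-like), as any matched design would.

Microsatellites: stable loci follow a geometric stutter ladder
(rate 0.15 per repeat unit over ±2 units). Unstable loci move 90% of
the tumor-derived reads to a novel expanded allele (offset ≥ 5 repeat
units, carrying its own stutter), the mixing weight being the sample's
tumor fraction. This makes instability separable exactly at the
benchmark operating point — at 10% purity the novel modal allele sits at
≈ 6–7% of depth against a ≈ 3.4% qualifying threshold (z ≈ 4 at 800×) —
while at high purity the novel cluster's own stutter keeps the allele
count elevated. Real MSI loci are messier (partial shifts, heterozygous
expansions, length-dependent stutter); passing benchmarks on this
generator demonstrate the scoring and dilution machinery, not clinical
performance.

What the generator does not emulate: fragment-length signal, GC and
mappability bias, subclonal copy-number states, multi-region phylogenies
of longitudinal samples, and panel-design detail. Cohort-level clinical
rates (ctDNA detection rates, per-line alteration fractions) depend on
patient data and are out of reach of any desk-scale simulation; the
package therefore validates mechanisms, inversions and operating points
rather than reproducing cohort epidemiology.

## Numerical conventions

Segments are 0-based half-open, variants 1-based (VCF). Mirrored BAF
lives in [0.5, 1]. All detection thresholds compare inclusively (≥);
the subclonality rule is strict (<). Weighted medians resolve ties
toward the lower index after sorting. Fisher's exact test uses the
probability-mass two-sided definition, the rank-sum test is exact for
small tie-free samples and normal-approximated with tie correction
otherwise (both via scipy, cross-checked in the tests against exhaustive
enumeration oracles). Identical seed and configuration reproduce
bit-identical simulations; all randomness flows through
`numpy.random.Generator` seeded from (seed, sample index).

## Problem sizes used in the shipped checks

The bundled benchmarks run at desk scale: 24 simulated normals, 50 MSI
and 100 MSS samples over 100 loci for the dilution operating point; 200
samples for tumor-fraction recovery and for biallelic precision/recall;
100 patients with 2 planted CH variants each for the filter round-trip.
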