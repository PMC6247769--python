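# plasmakit

Interpretation toolkit for cell-free DNA (cfDNA) liquid biopsies in
metastatic prostate cancer. Given per-sample variant tables (with
matched white-blood-cell depths), copy-number segments, structural
variants and microsatellite read-length histograms, plasmakit

* estimates the **circulating tumor DNA fraction** (`tf`) from
  copy-number-adjusted mutation allele fractions and from the CNA
  profile, and assigns detection tiers (point mutations detectable at
  tf ≥ 0.02, LOH at ≥ 0.10, homozygous deletions at ≥ 0.20);
* calls **microsatellite instability** with a baseline-referenced,
  mSINGS-style per-locus score and benchmarks the caller by read-level
  in-silico dilution;
* classifies variant **impact and clonality** (subclonal iff allele
  fraction < tf/4, structural variants after median allele-fraction
  adjustment) and calls per-gene **biallelic inactivation** from
  mutations, SVs, LOH and homozygous deletions;
* filters **clonal-hematopoiesis false positives** by discovering
  variants in matched WBC DNA against pooled healthy donors, excluding
  likely-germline calls (WBC allele ratio > 25% outside hotspots) and
  validating the rest in cfDNA;
* computes cohort statistics (two-sided Fisher exact, Spearman rho,
  one-sided Wilcoxon rank-sum) and assembles per-line-of-therapy
  reports.

Everything is exercisable without patient data through a seeded
synthetic-cohort generator (`plasmakit.simulate`) that plants known
tumor fractions, MSI status, gene zygosity and CH variants, and emits
the same TSV/VCF formats the readers consume.

The core quantitative relations: a variant on `m` of `CN_t` tumor
copies has expected allele fraction

    VAF = m·tf / (CN_t·tf + 2(1−tf))

and a segment at tumor copy number `CN` has coverage ratio
`r = (CN·tf + 2(1−tf))/2` and mirrored B-allele fraction
`BAF = (M·tf + 1−tf)/(CN·tf + 2(1−tf))`. All estimators are closed-form
inversions of these, combined as `tf_final = max(tf_vaf, tf_cna)`.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
from plasmakit import (SimulationConfig, simulate_sample, run_ch_filter,
                       estimate_tumor_fraction, interpret_sample)
from plasmakit.simulate import TS_GENES

cfg = SimulationConfig(seed=11, n_patients=1, true_tf=0.40)
sample = simulate_sample(cfg, 0)

candidates, filtered = run_ch_filter(sample.variants, sample.somatic_calls)
est = estimate_tumor_fraction(filtered.tumor_variants, sample.segments)
print(f"tf_vaf={est.tf_vaf:.3f}  tf_cna={est.tf_cna:.3f} "
      f"tf_final={est.tf_final:.3f}  method={est.method}")

statuses = interpret_sample(filtered.tumor_variants, sample.svs,
                            sample.segments, est.tf_final, genes=list(TS_GENES))
for gene in TS_GENES:
    print(gene, statuses[gene].zygosity_call,
          "| truth:", sample.ground_truth.gene_zygosity[gene])
```

prints

```
tf_vaf=0.414  tf_cna=0.392  tf_final=0.414  method=vaf
TP53 wild_type | truth: wild_type
PTEN monoallelic | truth: monoallelic
RB1 wild_type | truth: wild_type
BRCA2 biallelic | truth: biallelic
ATM wild_type | truth: wild_type
```

The sample was simulated at true tumor fraction 0.40; the mutation-based
estimate (0.414) slightly exceeds the CNA-based one (0.392) so the
`vaf` route sets the final value, which clears all three detection
tiers. One planted clonal-hematopoiesis variant was discovered in the
matched WBC reads, validated in cfDNA and removed from the
tumor-attributed profile before estimation, and the planted zygosity of
all five tumor suppressors is recovered.

The same flows are scriptable from the shell:

```sh
plasmakit simulate --seed 2 --n-patients 10 --out-dir cohort/
plasmakit tumor-fraction --variants cohort/S0000.somatic.tsv \
    --segments cohort/S0000.segments.tsv --out tf.tsv
plasmakit msi-dilution-benchmark --seed 2 --out bench.tsv
plasmakit report --in-dir cohort/ --out-dir report/
```

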