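# tissuevar

Variance-component decomposition and study-design tools for nested
tissue methylation/expression profiling.

Molecular profiles of heterogeneous tissues — endometrium, endometriotic
disease tissue, subcutaneous fat — vary for three distinct reasons:
differences between individuals, cellular heterogeneity within a physical
tissue sample, and technical noise between arrays. Telling these apart
requires a nested design in which tissue samples are *split* before
extraction and a subset of extracted splits is run on replicate arrays.
`tissuevar` implements the full analysis for such designs, for researchers
planning or analysing tissue-based EWAS/expression studies:

* per-probe decomposition of variance into between-individual (σ²_A),
  within-tissue/split (σ²_B) and technical (σ²_E) components by maximum
  likelihood under the nested linear mixed model

  y_isr = μ + a_i + b_is + e_isr,  a~N(0, σ²_A), b~N(0, σ²_B), e~N(0, σ²_E)

* sample-level QC filters (DNA yield > 1000 ng, call rate > 98 %,
  RIN > 7, housekeeping signal ≥ 10,000) and quality–covariate scans;
* structure analysis: per-tissue PCA (prcomp conventions), complete-linkage
  hierarchical clustering, label-swap outlier flagging, PC–covariate
  association (menstrual phase, age, smoking, BMI, WHR, case status);
* per-probe differential methylation/expression (OLS with covariate
  adjustment, paired analysis, Bonferroni/Benjamini–Hochberg correction,
  fold-change classification);
* variance-informed power: two-sample t-test power at Bonferroni-corrected
  α via the noncentral t distribution, detectable-probe fractions and
  required-n solving;
* a synthetic-data generator that emulates the nested split/replicate
  study layout with known per-probe variance components, covariate
  effects and spiked differential probes, so every stage is testable
  without access to raw cohort data.

## Worked example

Simulate the reference DNA-methylation layout (96 arrays: 88 extractions
from 24 women across three tissues, plus 8 technical replicates), run QC,
decompose endometrium probes and summarise the top-10 % most variable:

```python
import numpy as np
from tissuevar import (generate_dataset, study_methylation_params, qc_dna,
                       average_profiles, decompose_dataset,
                       rank_variable_probes, summarize_components,
                       PowerSpec, detectable_fraction)

data = generate_dataset(study_methylation_params(seed=7, n_probes=300))
kept, report = qc_dna(data.dataset)          # QC retained: 96 / 96
endo = kept.filter_tissue("endometrium")
decomp = decompose_dataset(endo)             # per-probe (σ²_A, σ²_B, σ²_E)
averaged = average_profiles(endo, level="all")
top10 = rank_variable_probes(averaged, 0.1)
print(summarize_components(decomp, top10, "endometrium", "top10").stats.round(4))
```

```
                     mean      sd
sigma2_individual  0.0052  0.0008
sigma2_split       0.0007  0.0005
sigma2_technical   0.0004  0.0002
prop_individual    0.8210  0.0717
prop_split         0.1203  0.0787
prop_technical     0.0587  0.0397
```

Among the most variable probes, 82 % of the variance is between
individuals, 12 % reflects within-tissue heterogeneity and 6 % is
technical — the pattern that justifies whole-tissue profiling for
moderately-to-highly variable sites. The fitted components then feed the
power calculation directly:

```python
sds = np.sqrt(decomp[["sigma2_individual", "sigma2_split",
                      "sigma2_technical"]].sum(axis=1))
spec = PowerSpec(effect=0.02, n_total=500, n_tests=len(sds))
print(detectable_fraction(sds.to_numpy(), spec, n_grid=[100, 500, 1000]).curve)
```

```
      n  effect  n_detectable  n_probes  fraction_detectable
0   100    0.02             0       300             0.000000
1   500    0.02            19       300             0.063333
2  1000    0.02           229       300             0.763333
```

i.e. with these per-probe SDs, a 2 % methylation difference (β = 0.02) at
80 % power and Bonferroni-corrected α is detectable in none of the probes
at 100 total samples but in 76 % of them at 1000 — the detectable
fraction is driven entirely by the per-probe SD distribution.

The same stages are available as a CLI
(`tissuevar simulate | qc | variance | pca | cluster | diff | power`), and
`tissuevar pipeline --config config.yaml` runs the whole chain with one
master seed and a run manifest.

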