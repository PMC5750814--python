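# Methods

## The nested variance model

Each observed profile value for one probe is modelled as

    y_isr = mu + a_i + b_is + e_isr

where `i` indexes individuals (strictly, individual × tissue samples —
each tissue is decomposed separately), `s` splits of the physical sample,
and `r` replicate arrays of an extracted split. The random effects are
independent Gaussians: `a ~ N(0, s2_A)` between-individual, `b ~ N(0,
s2_B)` within-tissue (cellular heterogeneity between splits), `e ~ N(0,
s2_E)` technical. Equivalently, `y` is multivariate normal with
covariance `s2_A J_individual + s2_B J_split + s2_E I`.

Per-probe fits use maximum likelihood (the default; REML is a flag — see
below). The likelihood is evaluated exactly in O(#splits) time by
factorising over individuals: within-split contrasts are iid `N(0,
s2_E)`, and the split means of individual `i` have covariance
`s2_A J + diag(v_s)` with `v_s = s2_B + s2_E / n_s`, handled by the
Sherman–Morrison identity. The grand mean is profiled out by GLS, leaving
a numerical maximisation over at most three log-variances (Nelder–Mead,
two starts: method-of-moments and an equal split of the total variance).

Boundary handling: whenever an estimate approaches zero (below 1e-6 of
the total variance), the model with that component pinned at exactly 0 is
refitted and kept if its likelihood is not worse; boundary estimates are
therefore reported as exact zeros, never as tiny positive numbers.
Exact-fit degeneracies (identical replicates, or identical split means
with no technical noise — possible only in constructed fixtures) are
detected up front and reduced to the closed-form one-way ML solution; for
an all-constant probe all components are 0 and the log-likelihood is
reported as +inf (a documented sentinel, mirroring the -inf sentinel for
a zero total variance asserted on non-constant data).

Identifiability follows the design, not a convention: with no replicated
split anywhere, `s2_B` and `s2_E` are confounded and only their sum is
reported (fields NaN, `confounded = "split+technical"`,
`sigma2_confounded` carries the sum); with no multi-split individual,
`s2_A` and `s2_B` are confounded analogously. A confounded sum of
exactly zero is the one case where the split into exact zeros is unique,
and it is reported as such. Components are never silently split.

ML variance components are biased low by O(1/I) in the number of
individuals because the mean is estimated; `reml=True` maximises the
restricted likelihood instead, which removes the leading bias term. ML is
the default because the headline decomposition is defined that way; REML
matters for small-I bias-sensitive uses and is verified by simulation in
the test suite.

Cross-checks: the log-likelihood is tested against a dense
multivariate-normal density oracle, the fitted maximum against an
independent grid+polish brute-force maximiser on small designs, and one
fixture against lme4's `lmer` (ML, `VarCorr`) via Rscript.

### Analysis scale

Methylation is analysed on the beta scale, matching the convention of
expressing effect sizes as beta differences (0.02 = 2 %); a logit
(M-value) option exists in the generator and the matrix reader accepts
either scale. Expression is analysed as log2 intensities.

### Probe-variability ranking

The top-50 %/10 % most-variable-probe subsets are ranked by empirical
variance across *split/replicate-averaged* independent samples (one
profile per individual × tissue). Averaging first prevents technical
noise from dominating the ranking; ties break lexicographically by probe
ID so the ranking is deterministic. Subset sizes are
`ceil(fraction × n_probes)`, so the top-10 % set is always nested in the
top-50 % set.

## Synthetic-data generator

The generator emulates the nested study layout: 24 women (16 cases, 8
controls); endometrium and fat contributed by 8 cases and 8 controls,
disease tissue by all 16 cases with endometrioma/peritoneal subtypes; all
endometrium and disease samples and half the fat samples split in two (88
DNA extractions), plus 8 replicate arrays = 96; the expression layout is
32 endometrium extractions plus 7 replicates = 39. Replicates attach to a
random subset of splits (`replicated_fraction`, or an exact count).

Probe baselines on the beta scale are drawn from a
low/intermediate/high mixture (0.15 / 0.5 / 0.85 by default) to mimic
the bimodality of array beta values; values are truncated to [0, 1] and
the generator warns if truncation exceeds 5 % of values (a logit-normal
variant avoids truncation at the cost of non-additive components).
Covariate effects (age, smoking, case status, menstrual phase as two
indicator contrasts vs the menstrual baseline) are linear on the analysis
scale and hit a declared fraction of probes; differential spikes add a
fixed group contrast to a probe block and are recorded, along with the
generating `(s2_A, s2_B, s2_E)`, in a truth table returned with every
dataset.

Baseline QC fields are drawn so that un-spiked samples pass the filter
thresholds; QC failures are injected explicitly (`spike_qc_failures`), so
retention counts in fixtures are exact by construction.

What the generator does **not** emulate: probe-level array chemistry,
chip/batch effects, spatial artefacts, genomic autocorrelation between
probes, or non-Gaussian heavy-tailed noise. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artefact of real arrays.

## Menstrual-phase handling

Cycle day is rescaled linearly to a canonical 28-day cycle
(`d' = round(d × 28 / length)`) and binned: menstrual 1–7, proliferative
8–14, secretory 15+. Linear rescaling is the simplest monotone mapping
that preserves the printed bin edges; missing cycle days yield a missing
phase, never a guess. Samples within a configurable day window of a bin
edge can be re-classified from expression structure: they adopt the
majority phase of their k nearest neighbours (default k = 3) in PC1–PC2
space.

## Structure analysis

PCA treats samples as observations and probes as centred (by default
unscaled) features, via SVD — the conventions of R's `prcomp` with
default settings; component signs are fixed by making each component's
largest-magnitude loading positive. Clustering is agglomerative with
complete linkage on Euclidean distances between averaged profiles;
samples are sorted by ID first so ties resolve deterministically.

Outlier flagging reconstructs the exclusion of likely tissue swaps: cut
the tree at k = number of tissues and flag any sample whose cluster's
majority tissue label differs from its own (ties flag nothing).
PC–covariate association uses Pearson correlation for continuous
covariates and one-way ANOVA of PC scores on categorical ones; both
per-PC p-values and the per-covariate minimum over the tested PCs
(default: the first two) are reported, since either convention may be
wanted.

## Differential analysis

Per-probe OLS on averaged independent samples: intercept + two-level
group indicator (+ covariates; phase enters as indicator contrasts). The
group coefficient is the effect (beta difference or log2 fold change);
two-sided t tests; with no covariates this reproduces the classic pooled
two-sample t test exactly. Rank-deficient designs (a covariate confounded
with the group) raise an error naming the collinear terms. Paired
analysis blocks on the individual, i.e. the one-sample t test on
within-pair differences; unpaired individuals are excluded with a
warning and counted.

Multiple testing: Bonferroni (the methylation convention here) or
Benjamini–Hochberg step-up FDR (the expression convention); both
available for either assay. Zero-residual probes — possible in tiny
fixtures — report p = 0 (effect ≠ 0) or 1 (effect = 0) with a
`zero_residual` flag and the df alongside, rather than NaN. No
empirical-Bayes variance moderation is applied by default; the model
structure, not the moderation, is the object of study here. Direction
labels are hyper/hypo on the beta scale and up/down on the expression
scale; fold change is `2**|log2 effect|` (≥ 1, direction carries the
sign) with a strict `>` threshold flag.

## Power

Two-sided two-sample t-test power at per-test
`alpha = alpha_family / n_tests` (Bonferroni), from the noncentral t
distribution with `df = 2n - 2` and noncentrality
`delta = effect / (sd * sqrt(2/n))`. Where scipy's noncentral-t CDF loses
accuracy (extreme tails at Bonferroni-scale alpha), the tail probability
is recomputed by numerical integration over the chi-square denominator.
Limits are by convention: sd = 0 gives power 1 for a nonzero effect and
alpha for a null effect; effect = 0 gives power = alpha (size).

The SD entering the per-probe power is the *total single-sample* SD,
`sqrt(s2_A + s2_B + s2_E)`, because a case/control study takes one
sample per individual; a between-individual-only option covers
averaged-replicate designs. "Sample size 100/500/1000" means total
samples split equally into two groups (50/250/500 per group); a
`per_group` flag switches the interpretation, since either reading is
defensible. The detectable fraction is the share of probes with power ≥
the target (default 0.8); `required_n` inverts the power function by
doubling + bisection to the smallest integer per-group n.

## Reference recovery experiment and problem sizes

The acceptance script and the corresponding test simulate 2,000 probes on
200 individuals × 2 splits with a replicate on half the splits — large
enough that the mean ML estimate across probes pins each component to
about ±0.005 (Monte-Carlo SE), small enough to run in about a minute per
scenario on one CPU — with generating components set to the top-10 %
summary values (methylation 0.84 / 0.18 / 0.06; expression 0.48 / 0.27 /
0.30). Null-calibration checks use 200 replicates of 1,000 null probes at
16 vs 14 samples; the Monte-Carlo power oracle uses 200,000 simulated t
tests per setting.

## Known limitations

* The variance decomposition assumes Gaussian components on the analysis
  scale; beta values near 0/1 violate this, which is why the ranking and
  recovery work is done where variability is moderate to high.
* Random effects are nested only; crossed designs (e.g. chip effects
  shared across individuals) are out of scope.
* The decomposition is unadjusted for covariates by design; covariate
  structure is handled in the differential and PC-association stages.
* Power calculations assume equal group sizes and a common per-probe SD
  across groups; FDR-based average power is not implemented.
* Cohort-specific findings (specific probe counts, gene lists, pathway
  enrichment) require the original raw data and are outside what
  synthetic recovery can or should reproduce.
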