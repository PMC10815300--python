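# Methods

## Measurement model

Each of the five markers (ELOVL2, FHL2, KLF14, C1orf132/MIR29B2C, TRIM59) is
a single CpG interrogated by single-base extension (SBE/SNaPshot) after
bisulfite conversion. In the electropherogram the methylated and unmethylated
alleles appear as peaks on two nucleotide channels, and the methylation level
is estimated as the intensity fraction of the methylated-allele peak:

    β = I_meth / (I_meth + I_unmeth)

with I the peak **height** by default (peak area is accepted as an
alternative intensity). ELOVL2 and FHL2 are read as C (methylated) vs T;
KLF14, C1orf132 and TRIM59 are read on the opposite strand as G vs A. A
channel with no called peak contributes intensity 0 — a fully methylated or
fully unmethylated template legitimately produces a single peak — so β stays
defined whenever at least one peak exists; only a both-channels-absent
measurement is treated as missing. When software calls several peaks on one
channel, the tallest peak inside the locus' expected size window wins, ties
broken toward the smaller fragment; this deterministic rule is an
implementation choice, since peak-calling ambiguity has no canonical
resolution. No minimum-height analytical threshold is imposed (configurable
upstream of the package by filtering the peak table).

## Replicate design and QC

Each sample is measured four times: two independent bisulfite conversions,
each amplified twice. Before averaging, a two-tailed pooled-variance
two-sample t-test compares, per locus, all levels measured under conversion 1
against those under conversion 2 across the cohort (amplifications pooled
within conversion). The default significance level is α = 0.05; a failing
locus is flagged but, by default, its measurements are still averaged —
exclusion is a strict-mode decision left to the analyst, because a cohort-level
batch effect is a protocol problem, not a per-measurement outlier. A
per-sample variant of the test (2 vs 2 values) is provided but is not part of
the default QC path; with df = 2 it has very little power and is intended for
diagnosing individual samples.

Degenerate t-test inputs are resolved exactly as documented: zero pooled
variance with equal means gives t = 0, p = 1; zero pooled variance with
unequal means gives p = 0 and a `degenerate` flag rather than a 0/0.

Fully methylated and fully unmethylated control DNAs processed alongside the
samples verify the conversion chemistry. Pass bounds default to β ≥ 0.9 for
the methylated and β ≤ 0.1 for the unmethylated control at every locus; any
failing locus fails the batch, and a locus absent from a control is marked
unevaluable with a warning. The bounds are package defaults — conversion
controls are universally run but rarely given numeric acceptance criteria.

Replicates are combined by the unweighted arithmetic mean of the available
(present) per-locus levels.

## Age model

The age model is plain multivariate linear regression of chronological age on
the five averaged methylation levels:

    age = b0 + Σ_l b_l · β_l

The published buccal-swab model (trained on 30 of 60 Italian volunteers aged
23–70) ships as a built-in with its six constants stored verbatim as decimal
strings, and model JSON serialization preserves all values bit-exactly. New
models are fitted by ordinary least squares via an SVD-based solve
(`numpy.linalg.lstsq`); no regularization is applied, matching the original
modelling choice. Fitting requires strictly more complete samples than
parameters (n ≥ 7 for the five-locus model) and a full-rank design; samples
with incomplete profiles are excluded with a logged count. Predictions are
**not clamped**: a grossly overestimated or negative age is diagnostic
information (e.g., a blood-trained model applied to buccal material
overestimates by decades) and must not be silently repaired. Train/test
splitting is a seeded simple random partition (training gets ⌈n·f⌉ samples);
an age-stratified variant is available but off by default.

## Evaluation

MAD is the mean absolute deviation |predicted − chronological| in years,
reported overall and within the strata 23–30, 31–40, 41–50, 51–60 and 61–70
(integer endpoints, both inclusive; ages outside every stratum go to an
`other` bucket, possible with synthetic inputs). R² is defined as the squared
Pearson correlation between predicted and chronological age — the R² of the
fitted line in a predicted-vs-chronological scatter — not as 1 − SSE/SST
against the identity line. The two definitions differ off the training set,
and only the correlation form can legitimately be higher on a test set than
on the training set. Per-locus Pearson r is the sample correlation of
methylation level with chronological age; loci with fewer than 3 measurements
or zero variance are reported as undefined rather than 0.

## Synthetic studies

The generator emulates the study design end to end so the pipeline can be
exercised and tested without access to the original cohort:

- **Cohort**: n = 60 by default; ages uniform over 23–70 whole years
  (continuous optional); sex 50/50 and unused by the model.
- **Biology**: per-locus level = baseline + slope·age + N(0, σ²), clamped to
  [0, 1]. Defaults (see `src/snapage/data/default_synthetic.yaml`) were
  calibrated analytically from r = slope·sd(age) / √(slope²·sd(age)² + σ²) so
  that realized level–age correlation magnitudes at n = 60 land in the
  moderate-to-low band (|r| ≈ 0.28–0.60) reported for buccal swabs. C1orf132
  is modelled with a negative slope (methylation at this marker declines with
  age, consistent with its negative model coefficient); the other four slopes
  are positive. A configuration that clamps more than half the cohort at any
  locus triggers a warning because its realized correlations no longer
  reflect the nominal parameters.
- **Replicates**: 2 conversions × 2 amplifications; replicate measurement
  noise sd 0.01 (a free parameter — no replicate-level variance is published
  for this assay); an optional between-conversion batch shift of ±`shift`
  (conversion 1 low, conversion 2 high) for QC power studies.
- **Instrument**: per locus, a log-normal total intensity (mean 4000, sd 1200
  RFU) is split between the two channels in proportion to the replicate
  level, each channel multiplied by (1 + N(0, cv²)) with cv = 0.05, rounded
  to integer RFU and capped at a 30 000 RFU detector ceiling. Zero-intensity
  channels emit no peak row. Control samples (β ≈ 0.98 / 0.02) ride along in
  every generated peak table.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`, so a study is reproducible from its written
`config.yaml`.

What the generator deliberately does **not** model: PCR amplification bias,
dye-specific mobility shifts, stutter or pull-up artefacts, degraded-sample
dropout, or inter-individual heteroscedasticity of methylation with age.
Passing pipeline tests on synthetic data therefore demonstrates correctness
of the computation (quantification, QC, fitting, metrics) under the stated
noise model — not that the published model's accuracy figures would be
reproduced on a new human cohort.

## Numerical and testing choices

- The between-conversion test and Pearson correlations are computed with
  scipy; the test suite checks them against independently coded textbook
  formulas (pooled-t, covariance/σσ) to 10 significant digits, and the OLS
  fit against a brute-force normal-equations solve to 8 significant digits on
  random full-rank instances (n ≤ 50, p = 5).
- Parameter recovery is verified on cohorts whose ages are generated from the
  published constants with noise sd σ ∈ {1, 0.1, 0.01, 0} years sharing one
  standard-normal noise vector, making the coefficient error exactly linear
  in σ: the maximum absolute error must shrink monotonically and reach ≤ 1e−8
  at σ = 0.
- The end-to-end identity test (simulate with all noise terms zero → parse →
  quantify → average → predict) tolerates MAD ≤ 0.05 y against the
  generator's own noiseless predictions, the slack coming only from integer
  rounding of peak heights (≤ ~0.5/4000 per channel, amplified by the
  coefficient magnitudes to ≲ 0.03 y).
- QC power: with a ±0.2 between-conversion shift injected at n = 30, the
  cohort-level test at α = 0.05 must reject at every locus in >90% of 100
  seeded simulations (in practice it rejects in essentially all of them).
- Problem sizes in the test suite (cohorts of 4–60, 100–200 Monte-Carlo
  repetitions) were chosen as the smallest sizes at which the statistical
  assertions are stable; the whole suite runs in a few seconds.

## Known limitations

- The package starts from called peak tables; it does not parse raw .fsa
  traces or perform peak calling or size-standard fitting.
- No correction or normalization of methylation levels is applied (none is
  used in the original protocol), and no prediction intervals are produced.
- The published model is specific to buccal material and the studied
  population; the package intentionally ships no other models, though any
  linear model can be loaded from JSON.
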