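# Methods

## Quantification model

A TMT 10-plex contains six plasma channels (126–129N) and four calibrant
channels (129C, 130N, 130C, 131) carrying a pooled PBMC lysate at
fractions 1/21, 4/21, 6/21 and 10/21 of total protein. Reporter
intensities are treated as proportional to (protein abundance) ×
(peptide ionisation efficiency) × (channel loading), multiplied by
log-normal measurement noise.

**Impurity correction.** Isotopic cross-talk mixes channel signals as
`observed = M · true` for a column-stochastic-ish, diagonally dominant
10×10 matrix `M`. Correction solves this linear system per PSM. Negative
solutions are set missing rather than clamped to zero: a negative
abundance is physically impossible and a zero cannot enter a log ratio.
Rows with any missing channel pass through uncorrected (with a logged
count) because the system is then underdetermined.

**Calibrant scaling and referencing.** Within each MS run, each calibrant
channel is multiplied by a scalar equalising its median (over PSMs) to
the grand median of the four channel medians. The target is arbitrary —
any common level cancels in the downstream ratios — but the grand median
keeps the run on its native intensity scale. The per-PSM reference is the
median of the observed scaled calibrant intensities, a mid-point statistic
robust to one aberrant channel; the mean is available as an alternative
reading of "mid-point". A PSM with fewer than two observed calibrant
values is unquantifiable. Sample ratios are `log2(intensity / reference)`;
with calibrant loadings `f = (1,4,6,10)/21`, a noise-free sample loaded at
fraction `g` yields exactly `log2(g / median(f))`.

**Rollup.** PSM ratios aggregate to peptides by the median over PSMs of
the same sequence (robust to elution-profile and run-to-run variation);
peptides aggregate to genes by the trimmed mean (trim factor 0.2, i.e.
`floor(0.2·n)` values cut from each tail) over peptides that are
non-phosphorylated and map uniquely to one gene. Phosphopeptides are
excluded because site occupancy changes confound abundance; shared
peptides because their signal is a mixture over proteins.

## Pre-processing

**Missingness filter.** A feature is removed when, in at least one
experimental group (Class × Stage cell), its missing fraction strictly
exceeds 0.35. The gate is per group — a feature well observed in three
groups but absent in the fourth cannot be imputed credibly there.

**kNN imputation (k = 2).** Features act as neighbours, within the
columns of the missing cell's group. Distance between two features is the
Euclidean distance over columns observed in both, normalised by the
number of shared columns (comparable across missingness patterns);
candidate donors must be observed at the target column; ties break by
feature order; with no eligible donor the feature's within-group observed
mean is used, with a warning. This matches the common features-as-
neighbours convention for expression matrices; samples-as-neighbours is
the other reading and is intentionally not the default.

**Batch/channel correction.** Per feature, least squares of the value on
group + batch (plex) + channel (treatment coding, aliased columns dropped
with a warning), subtracting only the batch and channel fits — the
`removeBatchEffect` semantics with groups protected. One refinement:
when plexes nest inside a group factor level (here, whole plexes are
early- or late-stage), part of the batch fit lies in the group space and
is unidentifiable from a genuine group effect; subtracting it would
impose an arbitrary reference-plex convention. The correction therefore
removes only the group-centred component of the nuisance fit (up to one
overall constant), which leaves fully crossed designs untouched and
avoids manufacturing stage effects in nested ones.

**Corrected data are for looking, not testing.** Values that have had
per-gene nuisance fits subtracted carry silently reduced residual degrees
of freedom; tests run on them are anti-conservative (measured null
raw-p < 0.05 rates of 0.06–0.36 through this pipeline). The corrected
matrix therefore feeds PCA, QC and exported displays, while inference
runs on the uncorrected matrix with nuisance factors in the model
(below). This follows the standard guidance for linear-model batch
handling in expression analysis.

**QC.** Per sample, the median (location) and IQR (scale; linear-
interpolation, type-7 quartiles — stated because the outlier flags depend
on the convention) of the feature distribution; a sample is a strong
outlier when either metric is more than three sample standard deviations
from its across-sample mean. Note a single aberrant sample among n can
reach at most `(n-1)/sqrt(n)` SDs, so the rule needs n ≥ 11 to be able to
flag anything; at the study's 24 samples it can. Outliers are reported
and only excluded on request.

**PCA.** Feature-centred SVD; variance fractions `s_i²/Σs_j²`; the sign
of each component is fixed by making its largest-magnitude loading
positive.

## Differential expression

Per gene, OLS of the log2 ratio on clinical covariates with treatment
coding (references: slow, early, control), collinear columns dropped
globally. Four standard comparisons run on sample subsets:

- fast vs slow at each stage: `value ~ Class + Age + Batch`. Class is
  crossed with plex within a stage, so the plex term belongs in the
  model; fitting it here (rather than testing pre-corrected data) charges
  the spent degrees of freedom to the fit.
- late vs early within each class: `value ~ Stage + Age`. Plexes nest in
  stage, so a batch term is confounded with the contrast; leaving it out
  keeps between-plex variation in the residual, which can only widen the
  error estimate (conservative).

**Moderation.** Residual variances are shrunk by empirical Bayes under
the scaled-F hierarchy: `s² | σ² ~ σ²·χ²_d/d`, `σ²` an inverse-χ² scale
mixture with prior df `d0` and scale `s0²`. Hyperparameters come from the
method of moments on `log s²` (closed-form mean/variance in digamma/
trigamma functions; trigamma inverted by Newton iteration). Posterior
variance `(d0·s0² + d·s²)/(d0+d)`; moderated t on `d0 + d` df. An
under-dispersed variance sample yields `d0 = ∞` (complete shrinkage); an
OLS-only switch disables moderation. The implementation is cross-checked
in the test suite against Bioconductor limma's `squeezeVar`.

**Selection.** BH step-up adjusted p-values are always reported.
Regulated features require |logFC| ≥ log2(1.3) and p < 0.05; the raw p
gates by default, with `use_adjusted_p` one flag away, since figure-
caption-style thresholds ("FC 1.3, p < 0.05") and table-style adjusted
p-values coexist in this kind of workflow.

## Enrichment

One-sided over-representation only (the workflow reports enrichment,
never depletion): `p = P(X ≥ k)` for the hypergeometric law on the 2×2
table `(k, n−k, K−k, N−n−K+k)`. The universe is the set of quantified
proteins, not the genome — quantifiability is a strong selection and a
genome universe would inflate every test. Terms overlapping fewer than 2
hit genes are ineligible and are excluded *before* BH (otherwise the
correction would depend on untestable terms). BH runs within each
ontology tag by default. An optional post-hoc redundancy collapse keeps,
among terms whose overlap-gene sets have Jaccard ≥ 0.5, the smallest-p
term; it is off by default because it is an editorial convenience, not
statistics.

## Synthetic-data generator

The generator emulates the study design: 4 plexes — two early-stage, two
late-stage — each with 3 fast and 3 slow subjects on randomly permuted
sample channels (avoiding systematic channel–class confounding) plus the
four-point calibrant series. Subjects are drawn clinically consistent:
ALSFRS-R respects the stage definition (early > 40, late < 35) and months
from onset is back-solved so the PRL lands in the class's range; ages are
N(60, 8²) years, matching the study's onset-age ranges.

Defaults (the simulated study conditions, fixed once):

| parameter | default | rationale |
| --- | --- | --- |
| proteins | 400 | desk-scale stand-in for the few-thousand-protein depth |
| peptides/protein | 2–6, PSMs/peptide 1–3 | typical plasma TMT coverage |
| class effect | 1.5 log2 on 10% of genes | study-scale effect and prevalence |
| stage effect | 1.0 log2 on a disjoint 10% | stage shifts are broad but weaker |
| age effect | 0 log2/year | off unless studied |
| PSM noise | 0.5 log2 sd | realistic reporter-ratio scatter |
| batch offsets | (0.2, −0.2, −0.25, 0.25) log2 | see below |
| MCAR | 2% | random missed quantifications |
| MNAR | p = 0.5 below 2^14 intensity | left-censoring dominates proteomics missingness |
| impurity spill | 0 (configurable < 1/3) | vendor matrices are near-diagonal |
| phospho / shared peptides | 5% each | minority eligibility exclusions |

Regulated genes always carry |log2 FC| ≥ log2(1.3) (the config rejects
sub-threshold effect sizes when `frac_regulated > 0`); unregulated genes
have exactly zero effect, so ground-truth recall and FDR are well defined.

**Batch offsets are centred within stage.** With two plexes per stage,
the between-stage mean of per-plex offsets is structurally confounded
with the stage effect — no correction can identify it — so the generator
only injects the estimable, within-stage component. A user supplying
uncentred offsets is simulating an unidentifiable confound, which the
pipeline will (correctly) absorb into the stage contrast.

What the generator does **not** emulate: chromatography and fragmentation,
identification error, calibrant-only proteins absent from plasma (a
`calibrant-only` flag would need a prevalence no study states), shared
longitudinal subjects (early and late samples are independent draws),
ratio compression from co-isolation interference, and channel-specific
labelling efficiency. Passing tests therefore demonstrate correctness of
the computations and calibration under this generative model, not
performance on real instrument data.

## Numerical conventions

- Missing values are NaN throughout; empty cells in TSV/CSV.
- Quartiles: linear interpolation (type 7). Trimmed mean: `floor(trim·n)`
  per tail. SD in QC flags: sample SD (ddof = 1).
- Median scaling is per MS run (run = plex in synthetic data, which does
  not simulate SCX fractions).
- BH via the standard step-up; Fisher tails via the hypergeometric
  survival function; both are checked against exact oracles (brute-force
  step-up; rational-arithmetic tail sums for all tables with N ≤ 30).
- Determinism: one integer seed drives the generator; identical configs
  produce byte-identical CSVs. The analysis pipeline is deterministic
  given its inputs (kNN ties break by feature order; sorts are stable).

## Problem sizes

Statistical checks run at 2000 genes × 12 samples with 200 replicates for
null calibration and FDR, 100 replicates for recovery, and a 400-protein
end-to-end pipeline run; these sizes give Monte-Carlo standard errors
well below the tolerances asserted (e.g. ±0.001 on the null p-rate).

## Known limitations

- The stage (longitudinal) contrasts compare whole plexes; with two
  plexes per stage, plex-level shared noise (e.g. the common per-PSM
  calibrant reference) is pseudoreplicated. The model keeps that
  variation in the residual, which is conservative on average, but a
  mixed model with a plex random effect would be the fuller treatment.
- The regulated gate on raw p (default) does not control FDR; the
  adjusted-p gate does, at a sensitivity cost at n = 6 per group.
- GO terms are flat sets; no graph propagation or cross-species ortholog
  mapping (term-name intersection only).
- The impurity model in the generator is nearest-neighbour symmetric
  spill; real vendor matrices are asymmetric with ±2 Da terms (the
  correction accepts any diagonally dominant matrix from CSV).
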