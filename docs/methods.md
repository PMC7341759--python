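# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-cohort generator, the defaults and the numerical choices, in
enough detail to reproduce or audit any number the package emits.

## Study design and data model

The pipeline assumes a paired design: each patient contributes one tumor
(T) and one non-tumor (NT) sample of the same log2-intensity expression
matrix (features × samples). Clinical phenotypes describe the tumor, so
every clinical test uses tumor samples only. Genomic coordinates are kept
0-based half-open (BED convention) throughout; detection flags, when
present, are per-cell Present/Marginal/Absent calls.

## Preprocessing

*Detection filter*: a feature is kept when its Present-or-Marginal
fraction is at least `detection_min_fraction` (default 0.5, inclusive; a
strict `>` variant covers the "expressed in more than 80% of samples"
style rule used for large validation cohorts). Without flags an intensity
floor can substitute. *Quantile normalization* maps each sample's sorted
values onto the across-sample mean of sorted vectors; tied values within
a sample receive the mean of the reference values at the ranks they
occupy, which makes the transform deterministic, rank-preserving and
idempotent. Filtering precedes normalization, so the reference quantiles
are computed on the features that survive detection.

## Differential expression

Per feature, the paired *t* statistic is `mean(d) / (sd(d)/√n)` on the
per-patient differences `d = T − NT` (complete pairs only), with a
two-sided Student *p* at *n* − 1 df. Degenerate differences follow fixed
conventions: zero spread with non-zero mean is an infinite-*t* sentinel
with *p* = 0; all-zero differences give *t* = 0, *p* = 1. Fold change is
reported on a signed linear scale, `2^Δ` when Δ ≥ 0 and `−2^−Δ`
otherwise, so |FC| ≥ 1 always and the sign is the tumor direction.
Benjamini–Hochberg adjustment runs across lncRNA and mRNA features as one
family by default (a per-biotype option exists); a feature is DE when
*q* < 0.05 and |FC| ≥ 2 (both thresholds configurable, the FC comparison
inclusive with a strict option).

## Clinical association

Eight raw characteristics collapse into five groups. The composite
"tumor properties" group is poor when **any** available sub-phenotype is
poor (size ≥ 5 cm, vascular invasion, stage 3/4) — the combination rule
inside the composite was a genuinely open choice; any-poor was selected
because a single adverse property suffices clinically, and per-sub-
phenotype testing remains available via the raw columns. Grade is poor at
3/4, capsule at incomplete/absent encapsulation, invasion when present.
Missing raw values propagate: a group label is missing only when no
sub-phenotype is available, and patients with a missing label are
excluded from that group's test only (pairwise deletion).

Categorical groups use a pooled-variance two-sample *t*-test of poor vs
good tumor expression with significance |FC| ≥ 1.5 and unadjusted
*p* < 0.05 (no multiplicity layer by design; an optional BH column is
emitted by the enrichment/DE machinery where wanted). Survival uses
univariate Cox proportional hazards with expression as a continuous
covariate and Breslow tie handling (ties are measure-zero for continuous
times; Breslow is the simplest well-defined choice). Monotone likelihood
(risk perfectly ordered by the covariate) is reported as a divergence
flag, constant covariates or < 2 events as not-testable. A logistic mode
(maximum-likelihood slope, Wald *p*) supports validation-cohort style
analyses of categorical phenotypes.

A feature is **potentially oncogenic** when DE-up and significantly
up-in-poor in ≥ 1 group (HR > 1 for survival), a **potential tumor
suppressor** when DE-down and down-in-poor; direction-discordant
significance never contributes.

## Co-expression and cis annotation

Pearson correlation is computed across all samples (T and NT pooled,
2*n* columns) by default — the common guilt-by-association choice; the
shared tumor contrast then dominates, which is why strong pairs are
essentially always positively correlated — with a tumor-only option.
Pairs at |R| ≥ 0.9 are "strong"; the same operation at |R| ≥ 0.6 feeds
perturbation integration. The all-pairs computation is a blocked matrix
product over row-standardized features, numerically identical (1e−9) to
feature-by-feature correlation and fast enough that 1,500 × 1,983
features over 98 samples completes in seconds. Constant features have
undefined correlation and are skipped with a log message. A pair is *cis*
when its mRNA is the lncRNA's nearest protein-coding gene: same
chromosome, minimal interval gap (0 when overlapping), ties broken by
smaller start then feature id; the search is strand-agnostic.

## Networks, concordance, master regulators

Edges are strong pairs whose lncRNA is classified oncogenic or
suppressor. Components of the resulting bipartite graph are classified by
their lncRNAs' tumor direction (all up → oncogenic, all down →
suppressive, else mixed — mixed components are reported, not dropped).
**Concordance** is counted at the mRNA level: the fraction of member
mRNAs that share at least one direction-concordant significant clinical
group with at least one correlated lncRNA in the component. An edge-level
variant and a pooled across-component figure are also computed, since
"fraction of concordant mRNAs" can be read per network or overall.

A **master-regulator set** is returned only for components passing three
gates — ≥ `min_mrna` member mRNAs (default 20; "large" is not otherwise
quantified, and the motivating positive example has 91 mRNAs while the
negatives have ≤ 9), concordance strictly above 0.8, and ≥ 1
significantly enriched gene set when an enrichment table is supplied —
and is the greedy set cover of the component's mRNAs by lncRNA
neighborhoods (largest marginal coverage first; ties by total degree,
then name). Greedy is deterministic and within ln *n* of optimal; an
exhaustive option exists for components with few lncRNAs.

Phenotype-unique lncRNAs are those whose concordant-group set is exactly
one group; their correlated mRNAs are unioned per group and DE direction.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k), computed by integer/rational summation so small-universe
values are exact. The background universe is all detection-filtered
mRNAs present in the GMT collection — the standard conservative choice
when the original database background is unknowable. Raw *p* is compared
to 0.01; a BH column is emitted for optional use.

## Synthetic cohort generator

Feature values follow

    x_fs = μ_f + b·z_s + Δ·1[tumor] + φ·1[tumor, poor patient] + u_{f,patient} + ε_fs

* μ_f ~ Uniform(6, 14) log2 units (typical microarray intensity range).
* ε ~ N(0, σ) with σ = `feature_noise_sd` = 0.3 log2 by default — array
  replicate-level noise; the paper's platform distribution is unknown, so
  the Gaussian log2 model is a modeling choice.
* z is one latent factor per module and sample, standardized to zero mean
  within each tissue compartment and unit variance overall. Standardizing
  within tissue makes the planted shift Δ the only systematic T−NT
  difference (otherwise the factor's sampling noise moves every member's
  fold change coherently), and unit variance makes the within-module
  correlation exactly `r = b²/(b²+σ²)` in expectation, with
  `b = σ·√(r/(1−r))` solved from the configured `target_r`.
* u is a per-feature, per-patient biological effect (SD
  `biological_sd` = 0.5 log2) shared by a patient's T and NT samples and
  applied to non-module features only — module members' patient-level
  biology *is* the factor. It cancels from the paired test but keeps
  unrelated background-DE features from correlating strongly merely by
  sharing the tumor contrast; without it every pair of same-direction
  background-DE features correlates near 0.9 in pooled samples, which no
  real cohort shows.
* Background DE: a `de_background_fraction` (default 5%) of non-module
  features get a ±1.5 log2 tumor shift with random sign.
* Phenotype links: for a linked group, patients are labeled poor by
  thresholding their tumor-sample factor at `poor_quantile` (median).
  The link direction follows the sign of the phenotype effect φ — high
  factor means poor for φ ≥ 0, low factor means poor for φ < 0 — so a
  suppressive (DE-down) module with negative φ is genuinely *lower* in
  poor patients. Raw clinical fields are then drawn consistently with the
  labels (poor tumor-properties patients always breach the 5 cm rule, so
  the any-poor composite reproduces the planted label exactly).
* Survival: event times are exponential with hazard
  λ₀·exp(Σ β_m·z_tumor) (λ₀ = ln 2 / 730 d⁻¹, a two-year median at
  z = 0), using the *tumor-sample* factor because phenotypes are tumor
  attributes. Censoring is independent administrative censoring
  C ~ U(0, c_max), with c_max solved so the expected censored fraction at
  the baseline hazard equals `censoring_rate` (default 0.3). Dependent
  censoring schemes (e.g. censoring at a uniform fraction of the event
  time) bias Kaplan–Meier estimates and were deliberately avoided.
* Annotation places each module's first lncRNA/mRNA pair adjacent on
  chr1 (a guaranteed cis case) and everything else round-robin over
  chr2–chr22 at 1 Mb spacing. Gene sets include one pathway per module
  (exactly its mRNAs) plus 10 random 20-gene decoys. Detection flags are
  all Present by default, with an option to mark the lowest-intensity
  cells Absent.

All randomness flows through a single seeded generator in fixed order, so
the same configuration and seed give byte-identical files.

### What the generator does not emulate

Probe-level effects and multi-probe summarization, batch/array effects,
intensity-dependent (heteroskedastic) noise, mRNA-count overdispersion,
correlated clinical confounding between groups, and non-proportional
hazards. Passing recovery tests therefore demonstrates the pipeline's
correctness on its stated model, not robustness to those artifacts.

## Problem sizes used in tests and the acceptance script

The end-to-end checks run one cohort of 49 paired patients with 2,000
lncRNAs + 2,000 mRNAs (planted 5 × 91 oncogenic and 4 × 8 suppressive
modules), a 20-seed null sweep at the same scale (false-positive rate
over 400 features × 4 groups per seed), 20 survival-recovery cohorts and
5 correlation-calibration cohorts; unit fixtures use 6–12 patients with
tens of features. These sizes give stable Monte-Carlo estimates (e.g.
binomial SE ≈ 0.0004 on the pooled false-positive rate) while keeping a
full run in the tens of seconds.

## Known limitations

* The composite tumor-properties rule (any-poor) and the pooled-sample
  correlation default are documented choices among plausible
  alternatives; both are configurable.
* Cox fits use a general-purpose optimizer; instances near monotone
  likelihood are flagged rather than estimated.
* Enrichment treats gene sets as flat lists (no topology, no ranked
  statistics).
* Cross-cohort validation requires caller-supplied id matching between
  platforms.
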