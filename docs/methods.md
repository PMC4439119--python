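# Methods

This note documents the statistical model behind `morscreen`, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Data model and detection semantics

A qPCR panel is an assay × sample grid of quantification cycles (Cq);
lower Cq means higher abundance.  A well is **detected** iff a value is
present and ≤ the positivity cutoff (default 34 cycles).  Wells may be
absent outright (not amplified / exported as "ND") or present above the
cutoff; both count as not detected.  Cq values are stored at full
precision; on write, missing wells are emitted as `ND` and on read the
tokens `ND`, `NA`, `N/A` and blank are accepted case-insensitively.

FOC (frequency of occurrence) is the per-group count of samples in which
an assay is detected.  The panel partitions into:

* **excluded** — FOC < 3 in either group (too sparse for any statistics);
* **set A** — detected in at least 19/28 controls and 17/22 cases.  For
  other cohort shapes these thresholds generalize as the ceiling of the
  fractions 19/28 and 17/22 of the group size, since the absolute counts
  are only meaningful at that cohort shape;
* **set B** — passes the FOC ≥ 3 filter but misses a set-A threshold;
* **undetected** — never detected anywhere.

The reported panel detection rate is the floor of the percentage
("at least X% of the panel is present").

## Reference selection and normalization

Candidate normalizers are restricted to assays detected in every sample.
Each candidate's **stability** is

    stability = sqrt( mean_g (m_g − m)²  +  mean_g s_g² )

with group means m_g, grand mean m and within-group variances s_g² — a
two-way (group × residual) decomposition in the spirit of model-based
reference-gene selection: an ideal reference has no group effect and no
scatter, so a constant candidate scores exactly 0.  Only the *ranking*
contract is guaranteed; the exact numerical scale of other normalizer
tools is not reproduced.  Ties break by assay id (stable sort), and an
explicit reference list can always be supplied instead.

ΔCq(assay, sample) = Cq − arithmetic mean of the reference Cq values in
that sample.  Missing target wells stay missing.  In strict mode a
reference missing anywhere is an error; lenient mode averages the
available references per sample with a warning.  Because a per-sample
additive shift of all Cq values cancels exactly in this subtraction,
ΔCq — and everything downstream — is invariant to global efficiency /
loading offsets (the test suite checks this bit-exactly on a dyadic
grid, where floating-point addition is exact).

Fold change is 2^(−ΔΔCq) with ΔΔCq = mean ΔCq(case) − mean ΔCq(control);
calls are `up` iff FC ≥ t, `down` iff FC ≤ 1/t (default t = 1.5), with a
1e-12 relative guard so exact-threshold effects are not misclassified by
roundoff.  Two-sided two-sample t-tests (pooled variance by default,
Welch by flag) provide the volcano p-values.

## The Measure-of-Relevance screen

For one marker with values x (group 1) and y (group 2), pooled and
mid-ranked:

    MoR = | mean rank(x) − mean rank(y) | / SD(pooled ranks)

with the population SD in the denominator.  Properties: nonnegative,
symmetric in group order, invariant under strictly monotone transforms,
0 when all pooled values tie (zero rank dispersion is "no information",
not an error).  For complete separation at n = 5 vs 5 the value is
5 / sqrt(99/12) ≈ 1.7408; the default critical value d = 0.57 sits
between a conventional medium (0.5) and large (0.8) standardized effect.

Markers are sorted ascending by MoR into the *information chain* (ties
break by marker id); markers strictly above d are **informative**.  If d
exceeds the maximum MoR, nothing is informative.  The critical value is
a fixed configurable number by design; an alternative largest-gap rule
on the chain is provided but explicitly labelled non-canonical.  The
statistic itself is pluggable (`statistic=` hook) so a composite variant
adding dispersion terms can be swapped in; the rank-scale mean
difference is the default because it is the only form the screening
contract pins down.

CSF protein markers (total tau, p-tau, Aβ1–42) can be appended to the
marker table on their native pg/ml scale — the screen is rank-based and
therefore scale-free — and serve as positive controls.

### Reliability by subsampling

B subsamples (default 800; m = 15 per group, drawn without replacement)
are screened at the fixed d; RF = (times informative)/B, and markers
with RF ≥ 0.8 are **reliable**.  Each repeat uses an independent RNG
stream keyed on (seed, repeat index), and the draw runs over sample ids
in sorted order, so results are reproducible and independent of input
column order.  Repeats are sampled independently; at C(28,15)·C(22,15)
possible subsamples, collisions are irrelevant.  Two missing-value
policies: `none` evaluates each marker per subsample on detected values
only and counts it non-informative when either group retains fewer than
two; `group_mean` substitutes full-data within-group means first.
Substitution can only increase evaluability, never decrease it.

With m equal to the full group sizes and B = 1 the stage reduces exactly
to the single screen.

A consequence worth knowing: at cohort sizes 28/22 the full-cohort MoR
of a truly null marker has SD ≈ 0.29, and subsample MoR values are
strongly correlated with the cohort value.  Null markers therefore quite
often land at intermediate RF (a fifth of them above RF ≈ 0.2), while
genuinely shifted markers (≥ 1.5 cycles) separate cleanly at RF ≥ 0.8.
RF is a screening score, not an error-controlled test.

## Confirmatory MANCOVA

Responses are the selected markers after group-mean substitution
(samples × p, no missing cells).  The design is intercept + a single
group contrast + covariates (metric covariates centered; two-level
string covariates coded 0/1 — age and sex in the default pipeline), so
q model terms in total.  With E and H the residual and hypothesis
cross-product matrices (H obtained by refitting without the term),

    Λ = det(E) / det(E + H),
    F = ((1 − Λ)/Λ) · (n − q − p + 1)/p   ~  F(p, n − q − p + 1)

exactly for the single-df group hypothesis; at n = 50 and q = 4 this
gives the familiar (8, 39) / (9, 38) numerator–denominator pairs and
univariate follow-ups on F(1, 46).  Multi-df blocks (both covariates
jointly) use Rao's F approximation, exact for min(p, h) ≤ 2 — e.g.
df (16, 78) for two covariates and eight responses.  Univariate
follow-ups are Bonferroni-corrected: reject iff p < α/m with adjusted
p = min(1, m·p).  The family size m is configurable and defaults to the
number of responses in the family being tested; families are defined
per marker set because a single global family would contradict the
per-family reporting convention this pipeline follows.

Pearson correlations come with the t-based two-sided p and a Fisher-z
interval tanh(atanh r ± z/√(n−3)); r² is reported as an integer percent
of variance explained.  An optional per-analysis Cq inclusion cutoff
(e.g. 32 cycles) restricts the pairs to confidently quantified samples.
Demographics use pooled-variance t-tests from raw data or group
summaries (mean, SD, n) — the summary variant exists because published
cohort tables are only checkable from summaries — plus a χ² test for
sex counts.  Pooled variance is the default; Welch is a flag, and the
two genuinely disagree for high-variance protein markers.

## Classification

Linear discriminant analysis with priors proportional to group sizes
(equal priors by flag), reported as the resubstitution confusion matrix
with per-group and overall accuracy — resubstitution is the primary
metric because it is the convention for small-cohort discriminant
reports; an optional leave-one-out mode is labelled as such.  Each
marker also gets a concordance AUC, U/(n₁n₂) from mid-ranks with ties
counted half, oriented so AUC ≥ 0.5 (orientation reported).  ROC
coordinates are exported as TSV rather than plotted.

## The synthetic cohort generator

`simulate_cohort` draws Cq = μ_assay + s_sample + δ·1[case] + ε with
assay abundance μ in three tiers — references (Gaussian around 24
cycles), an abundant tier (around 26, the set-A analog, default 50
assays), and a dilute tail (around 37.5, SD 3) — a per-sample technical
offset s (SD 0.5, removed by normalization), planted group effects δ in
ΔΔCq cycles, and measurement noise ε (SD 1.0 cycles).  Dropout is
logistic in (true Cq − cutoff) at slope 0.7/cycle by default, so dilute
assays lose wells preferentially; missing-completely-at-random and
no-dropout models are available because real CSF missingness is not
characterized well enough to assert either mechanism.  At the defaults
this reproduces the qualitative census of a CSF panel: roughly a third
of 1178 assays detected at all, an abundant stratum of ~90 set-A assays,
a large set-B stratum, and a long excluded tail.  Covariates follow the
configured per-group Gaussians (defaults: age 61.0 ± 12.7 vs 72.1 ± 8.5
years; tau 308.9 ± 227.7 vs 708.5 ± 282.9 pg/ml; p-tau 52.6 ± 28.5 vs
92.0 ± 93.3; Aβ1–42 719.9 ± 406.7 vs 446.7 ± 164.1, clipped at
1 pg/ml), sex is stratified deterministically, and optional correlation
hooks couple a marker's log2 expression to a protein through a shared
latent Gaussian factor at a target within-group r.

What the generator does **not** emulate: pool-specific chemistry or
preamplification bias, inter-plate effects, miRNA-family correlation
structure (assays are independent given the sample offset), non-Gaussian
abundance distributions, and informative missingness beyond the
abundance-driven logistic.  Tests passing on this generator therefore
validate the *statistical machinery* — calibration under the null,
recovery of planted effects, invariances — not the biological claims of
any particular cohort.

## Numerical choices and degenerate inputs

* Ranks use scipy mid-ranks; the MoR denominator is the population SD.
* All tie-breaks (information chain, reference ranking) are stable sorts
  by id, so outputs are order-independent and reproducible.
* Zero pooled-rank dispersion → MoR 0; zero variance in both t-test
  groups with equal means → p = 1 ("flat"); all-tied ROC scores →
  AUC 0.5 with a degenerate flag; singular E or pooled covariance →
  a numerical error advising fewer/less-collinear markers.
* Every stochastic step (generator, reliability, pipeline) consumes an
  explicit integer seed; the same seed gives bit-identical output, and
  the full run configuration is serialized into the run report so any
  run is reproducible from the report alone.
* Default problem sizes in tests and the acceptance script (panels of
  30–200 assays, B = 200 repeats, 20 seeds, 2500 simulated families)
  were chosen as the smallest sizes at which the Monte-Carlo noise is
  comfortably below the tolerances being asserted.

## Known limitations

* The stability score ranks normalizer candidates plausibly but is not
  numerically compatible with other reference-selection software.
* The MoR composite here is the location-only rank form; published
  variants that add distribution-shape terms would need the pluggable
  statistic hook.
* Group-mean substitution underestimates within-group variance; the
  confirmatory stage inherits that optimism (no multiple-imputation
  alternative is provided).
* Resubstitution accuracy is optimistically biased by construction; use
  the leave-one-out mode for a less biased estimate.
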