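# Methods

## The statistical model

The unit of analysis is a CpG probe's beta value — the methylation fraction
β = M/(M+U+α), where M and U are methylated/unmethylated fluorescence
intensities and α ≥ 0 a stabilising offset (the platform's value is not
standardised, so `compute_beta_from_intensities` takes it explicitly).
Betas live in [0, 1]; percentage points (pp) are beta differences ×100.

In a discordant-MZ-pair design the affected co-twins (n = 6 by default) and
healthy co-twins (m = 6) are compared probe-wise by the variance ratio

    F = S²_affected / S²_healthy ,

referred to the upper tail of F(n−1, m−1). The orientation is fixed and the
test one-tailed: a rare, large, single-co-twin deviation (an epigenetic
outlier) inflates the affected group's variance, while excess variance in
healthy samples — which occurs genome-wide for unrelated reasons — must not
generate hits. The co-twins are treated as independent samples even though
the pairs correlate the two groups through shared effects; that sharing
makes the test *conservative* (shared variance inflates both S² terms
together, concentrating F near 1), never anticonservative, and it is the
form the discordant-twin literature uses. The cost is power, which the
design buys back through genetic identity: sequence variants cannot
masquerade as outliers.

Degenerate probes are mapped, not raised: zero healthy variance with
positive affected variance gives F = ∞, p = 0; two zero variances give
p = 1 with F undefined. A genome-scale scan must not abort on constant
probes; occurrences are counted in the scan result.

### Multiplicity

Storey q-values: π₀ (the null-probe fraction) is estimated from
π̂₀(λ) = #{p > λ}/(m(1−λ)) on the grid λ ∈ {0.05, 0.10, …, 0.95}, smoothed
by a cubic spline and read off at λ = 0.95, truncated to (0, 1]. The
q-transform is the step-up q₍ᵢ₎ = min_{j≥i} π₀ m p₍ⱼ₎/j; with π₀ = 1 it
reduces exactly to Benjamini–Hochberg, which the tests verify against a
brute-force oracle. Fewer p-values than grid points, or a non-positive
smoother estimate, fall back to π₀ = 1 with a warning.

### The outlier rule

A probe is called an outlier locus when q ≤ 0.05 **and** the
affected-minus-healthy range difference strictly exceeds 10 pp. The range
filter screens out statistically significant but sub-technical effects:
array measurements below ~10 pp are poorly reproducible and unlikely to be
functional. Both thresholds are configurable; the funnel (tested →
significant → range-filtered) is always recorded. Range differences are
computed from unrounded ranges and rounded only at reporting.

Each outlier probe is attributed to the affected co-twin with the largest
absolute deviation from the median of all discordant-pair samples (ties →
lexicographically smallest sample id, flagged).

## Cell-composition adjustment

Whole-blood methylation mixes K leukocyte types (default six: B, CD4⁺ T,
CD8⁺ T, monocytes, NK, granulocytes). Per-sample proportions w are
estimated per sample by constrained least squares against a reference panel
R over discriminating probes:

    min ‖R w − b‖²  s.t.  w ≥ 0,  Σw ≤ 1 ,

solved as NNLS on an augmented system in which a heavily weighted row
(10⁶) enforces Σw + s = 1 with a non-negative slack s; the slack absorbs
unmodelled types. An equality constraint is available (`constraint="eq1"`).
Noiseless mixtures are recovered to ~10⁻¹¹, verified in the tests against a
semi-analytic grid-search oracle.

The "average cell" adjustment then regresses each probe's betas on the
centered proportions and keeps the fit at the cohort-mean composition plus
the residual. Numerically the fit is an SVD projection with an absolute
singular-value cutoff (10⁻¹⁰), so a constant or collinear composition
contributes exactly nothing (the spec'd no-op case) and adjustment is
idempotent when nothing is clipped. An optional ridge penalty λ ≥ 0 on the
composition coefficients (default 0) shrinks along the singular directions.

**Robust pass (default on).** Ordinary least squares lets a single gross
outlier leak through the hat matrix into every sample's fitted value: with
34 samples and 6 covariates the projection has rank 6 regardless of the
composition's scale, and a 0.3-beta single-sample deviation then inflates
the healthy group's variance several-fold — the adjustment would launder
the very signal the scan exists to find, and no plausible effect would
survive it at this sample size. Therefore observations beyond 4 robust
z-units (median/scaled-MAD) of the first-pass fit are excluded when the
coefficients are re-estimated (the fit is still evaluated at all samples,
re-centered on the fitting subset). Genuine composition effects are
many-sample phenomena and are untouched; rare extremes keep their full
deviation. A consequence worth knowing: a sub-threshold chance deviation
that OLS would have partially absorbed can cross q ≤ 0.05 after robust
adjustment, so the adjusted *significant* count is not monotonically below
the unadjusted one — the final outlier calls are, because such flips never
pass the 10-pp range filter. Adjusted values are clipped to [0, 1] with a
clip counter.

## Preprocessing funnel

Three filters in a fixed order, each reported with its removal count:
detection quality (drop a probe if its detection p exceeds 10⁻⁴ in *any*
sample — the strictest reading, since no sample-fraction rule is standard),
autosome restriction (chromosomes 1–22 only; X/Y probes confound mixed-sex
cohorts), and completeness (drop probes with any missing value among the
discordant-pair individuals — the samples the scan uses). Probes missing
from the annotation are dropped with a warning by default. The per-stage
counts make any order-dependence inspectable.

## Pair validation

Candidates are re-examined in the concordant and healthy pairs. For each
(probe, pair), a co-twin is *outlying* when its robust z-score against all
out-of-pair samples (median, 1.4826×MAD) exceeds 3; a zero-MAD reference
falls back to a range rule. Patterns:

* `discordant_outlier` — exactly one co-twin outlying: the same signature
  the scan detects, so its presence in a validation pair invalidates the
  candidate;
* `shared_outlier` — both outlying and within 5 pp of each other: the
  signature of a low-frequency sequence variant or a shared exposure;
  reported (SNV-suspect) but not invalidating, since it is a genetic, not
  stochastic, signal;
* `normative` — everything else.

The 3-sigma and 5-pp defaults operationalise what is otherwise a visual
judgement; both are configurable. Note the finite reference (~32 samples)
inflates the robust z's effective tail ~3–4× over the Gaussian nominal
0.0054 per pair, so occasional false single-co-twin calls are expected
(~2% of probe-pairs) and a candidate's validation verdict at these defaults
is correspondingly strict.

## The synthetic-cohort generator

`generate_cohort` emulates the data structure the analysis assumes, not any
particular dataset:

| parameter | default | meaning |
|---|---|---|
| n_discordant/concordant/healthy | 6 / 4 / 7 | pairs, the study design |
| n_probes | 10,000 | desk-scale stand-in for ~473K array probes |
| baseline centers, weights | 0.05/0.50/0.92; 0.45/0.20/0.35 | hypo/intermediate/hyper mixture of probe means (logit sd 0.4) |
| pair_effect_sd | 0.25 (logit) | shared within-pair deviation (MZ identity) |
| noise_sd | 0.005 (beta) | per-call measurement noise |
| n_outlier_probes, outlier_delta | 20, 0.3 | single-co-twin shifts, sign away from the nearer boundary |
| dirichlet_concentration | 60 | per-sample composition around typical blood fractions |
| n_composition_probes, composition_effect | 200, 0.15 | probes tracking one cell type's proportion |
| missing_rate, detection_fail_rate | 0.001, 0.001 | funnel exercise |

Pair effects act on the logit scale (keeps boundary probes realistic);
noise and outlier shifts on the beta scale; everything is clipped to [0, 1]
with a counted number of clip events, and injected effects are recorded in
a `TwinTruth` manifest. The injected-shift magnitude 0.3 lands the affected
ranges in the mid-teens-to-40-pp window the published loci span.

What the generator does **not** emulate: Infinium probe-type chemistry
biases, batch effects, age/sex methylation structure, genuine biological
variance heterogeneity between probes beyond the mixture means. Passing
tests therefore demonstrate the statistical machinery under the assumed
noise model, not robustness to real-array artifacts.

Calibration and power experiments set `pair_effect_sd = 0` so the baseline
per-group sd is exactly the stated noise sd: shared pair effects correlate
the two co-twin groups and make the unpaired F-test conservative, which
would mask the test's intrinsic null calibration, and under them the
scan's power is lower than the independent-samples arithmetic suggests
(a documented property of the design, shown by `scan` on default cohorts).
The reference panel (`generate_cell_reference`, 100 probes × 6 types) is a
synthetic stand-in for a sorted-cell reference: a scaled identity block
guarantees identifiability (full column rank, pairwise column distance
≥ separation·√2).

## Problem sizes and reproducibility

Tests and the acceptance script run at 10,000 probes and 5–10 seeds —
sizes chosen so the full suite completes in well under a minute while the
binomial/power arithmetic stays meaningful; the generator scales to full
array size unchanged. Every stochastic step takes an explicit integer seed;
the pipeline writes a manifest (config hash, input checksums, seed, stage
timings) sufficient to reproduce a run byte for byte.

## Known limitations

* Power at 6-vs-6 is modest: a 0.3 shift on a 0.01 baseline sd has ~92%
  per-probe power at genome-wide q ≤ 0.05, so a handful of true loci per
  twenty are expected to be missed at desk scale.
* The F-test's independence assumption is violated by the twin pairing
  (conservatively so, see above); no paired variance test is provided.
* Betas, not M-values, are tested: the published protocol's scale, and the
  range filter is only meaningful on it, but variance at extreme means is
  compressed.
* The validation verdict depends on declared thresholds (z > 3, 5 pp), not
  on an externally calibrated error rate.
* mQTL and brain–blood concordance lookups are joins on user-supplied
  tables only; nothing is fetched.
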