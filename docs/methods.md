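# Methods

## Study design being modelled

Ten animals are measured in three inotropic states (baseline BL, dobutamine
Dob, verapamil Ver). For each state and each strain component
(longitudinal, circumferential, radial), two observers independently
analyse the same images, each twice, producing segmental strain values on
the 16-segment AHA model (apical cap excluded). All strain quantities are
in percent ("strain points").

## Aggregation

Global strain is the unweighted arithmetic mean of the 16 segmental values
— each segment weighs equally, not each basal/mid/apical level. Replicates
are averaged per segment before segment averaging; because both steps are
means over fixed index sets they commute, which the suite verifies. The
strict missing-data policy requires all 16 segments and names missing ones;
a lenient mode accepts ≥ 12 segments (configurable), since silently
averaging fewer segments would change the estimand. Sign conventions
(GLS/GCS ≤ 0, GRS ≥ 0) are checked as warnings only, so extreme synthetic
draws are not rejected.

## Agreement analysis

*Bland–Altman.* For aligned paired values the differences d = a − b give
bias `mean(d)`, `sd_diff` with the n−1 denominator, and limits of agreement
`bias ± z·sd_diff` with z = 1.96. Zero-variance differences are legal (the
limits collapse onto the bias); n < 2 is an error.

*ICC.* Computed from the two-way ANOVA mean squares (subjects × raters).
The default variant is two-way, absolute agreement, single measures —
McGraw & Wong's ICC(A,1) — the common default of mainstream statistical
software for agreement studies; consistency (C-1) and average-measures
(A-k, C-k) forms are selectable. 95% CIs use F-distribution quantiles, with
Satterthwaite degrees of freedom for the absolute-agreement forms;
average-measures CI bounds go through the Spearman–Brown map, whose pole at
r = −1/(k−1) is handled by reporting −∞ for bounds at or below it (the
k-rater mean's reliability is unbounded below there). Negative estimates
and CI bounds are reported as computed, without truncation at zero.
Estimates are verified in the suite against a deliberately loop-based
ANOVA-sums oracle (to 1e-10 on 50 random matrices) and cross-checked
against `pingouin`.

*Comparisons.* Inter-observer series pair each observer's
replicate-averaged global values; intra-observer series pair observer 1's
first and second analysis sessions (first-vs-second measurement, not
averaged pairs — with only two replicates per observer this is the only
within-observer contrast that leaves the sessions distinct). Agreement
adjectives: excellent ICC > 0.74, good 0.60–0.74 (inclusive), fair
0.40–0.59, poor < 0.40.

## Sample size

The implemented relation is n = round_half_away(2·f·σ²/δ²) with floor 1,
f = 10.5 for α = 0.05 and power 0.80, σ the SD of between-measurement
differences and δ the detectable change, both in strain points. The
factor 2 reflects that a detected change is a difference of two
measurements. This reading, the interpretation of δ as strain points
numerically equal to the nominal 5/10/15% relative change, and
half-away-from-zero rounding were selected by brute-force enumeration of
candidate readings of the published (typographically ambiguous) relation
against the published planning-table cells; the enumeration is frozen as a
test, and the selected reading is the unique candidate reproducing every
robust cell. f is a supplied table constant, not recomputed from normal
quantiles, because the published factor does not match standard two-sided
power tables and recomputing it would diverge from the modelled study.

σ can be supplied explicitly (the published pooled SDs 4.9/7.4/17.9 for
GLS/GCS/GRS are stored as design constants), derived as the SD of baseline
inter-observer differences, or Cohen-pooled from the two observers'
baseline SDs: √((SD₁² + SD₂²)/2). Dropout inflation is ceil(n/(1 − rate)),
default planning rate 0.25. Cells where the systematic observer bias
exceeds δ can optionally be suppressed (a change smaller than the bias is
not meaningfully detectable); by default all cells are computed.

## Synthetic-data generator

Each segmental reading decomposes as

value = μ(state, comp) + A(animal; state, comp) + S(animal, segment; …)
        + bias(observer; …) + e(animal, observer, replicate; …)

with A ~ N(0, τ²) the between-animal effect, S ~ N(0, segment_sd²) the
per-animal segment pattern (centred within each animal, so segment
dispersion never moves the 16-segment mean), and e ~ N(0, ε²) the
analysis-session error. All terms are Gaussian — the modelled study reports
only means ± SDs, which justifies nothing heavier-tailed.

Two deliberate model choices:

- **A and S are drawn per (state, component) cell**, since the published
  between-animal SDs differ per cell; a single per-animal effect could not
  realize them.
- **e is a session-level error**, drawn once per
  (animal, state, component, observer, replicate) and shared across that
  session's 16 segments: one analysis session places one set of contours,
  perturbing all segmental values together. This keeps the preset
  calibration ε = sd_diff/√2 meaningful at the global level; with
  per-segment-independent noise, averaging 16 segments and 2 replicates
  would shrink global difference SDs by √32 and the generated agreement
  tables would be unrealistically tight.

The preset configuration uses the published per-state means and
between-animal SDs (observer 1 column), observer-2 biases equal to the
negated published inter-observer mean differences (differences are
observer 1 − observer 2), and ε backed out of the published inter-observer
difference SDs as sd_diff/√2 (difference of two independent equal-noise
observers). The published intra-observer difference SDs imply somewhat
different ε per comparison; the preset uses the inter-observer values and
leaves that tension unresolved, so generated intra-observer rows track the
published ones only approximately. Under this model the replicate-averaged
inter-observer difference SD is ε (not √2·ε), i.e. somewhat below the
published values — the calibration favors the single-session relation the
recovery tests use. segment_sd defaults to 3 strain points, a mid-range
segmental dispersion consistent with visible basal-to-apical variation
without overwhelming the state effects; it cancels from all global-level
statistics by construction. One `numpy` Generator is seeded per `generate`
call with a fixed draw order, so a seed fixes the dataset byte for byte.

Parameter recovery is verified at n = 10 000 animals on the baseline GLS
cell (μ, τ within 0.15 strain points; bias within 0.05; single-session
difference SD within 2% of √2·ε). The tolerances are several sampling-SEs
wide for that cell; high-noise cells (e.g. radial strain under dobutamine,
where the SE of the mean alone is ≈ 0.23) could not meet them at this n and
are not asserted.

## What the synthetic data do and do not show

The generator reproduces the design shape and second moments; it does not
model image content, heart-rate-dependent tracking quality (the mechanism
behind poorer dobutamine reproducibility), non-Gaussian tails, or
state-correlated observer bias beyond the per-cell bias table. Passing
tests therefore demonstrate the correctness of the aggregation, agreement
and planning machinery under the assumed moment structure — not that real
CMR-FT data satisfy those assumptions. Published ICC point estimates are
deliberately not reproduced: per-animal raw data were never released, and
one published inter-observer ICC (−1.60 with k = 2) lies below the
single-measures floor of several standard formulations, so the exact
variant used there is unknowable. ICC behaviour is instead pinned by
oracle-equivalence and invariance properties.

## Numerical choices and scales

Half-away-from-zero integer rounding for required n; sample SDs with n−1
throughout; strict aggregation by default; ICC on complete matrices only,
with zero total variance an explicit error. Default problem sizes — 10
animals end-to-end, 10 000 for recovery checks, 50 random matrices for
oracle equivalence — keep the full suite under half a minute while leaving
the stochastic tolerances several standard errors wide.
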