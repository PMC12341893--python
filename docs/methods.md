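# Methods

This note documents the models, defaults and numerical choices behind
`semspace`, and what the synthetic-data experiments do and do not establish.

## Stimulus model

A word is a vector of nine psycholinguistic norms: concreteness (1–5),
valence, arousal, dominance (1–7), age of acquisition (years), log10
frequency, orthographic neighbourhood density (count), length (letters) and
prevalence (fraction of the population knowing the word). Classification
into the four stimulus classes applies the inclusion rules in this order:
frequency (log10 ≥ 1), prevalence (≥ 0.98), concreteness band (abstract
[1.5, 2.5], concrete [4, 5], middle of the scale excluded), valence band
(negative [2, 4), positive (4, 6]). Valence exactly 4 lies on the boundary
of both bands and is excluded as ambiguous. The classifier is total: every
finite rating vector maps to exactly one class or one exclusion reason.

The synthetic generator draws the two manipulated features from per-class
truncated normals (abstract ≈ 2.04 ± 0.3, concrete ≈ 4.4 ± 0.3; negative
≈ 2.6–2.8 ± 0.4, positive ≈ 5.2–5.3 ± 0.4) and the seven nuisance features
from class-independent truncated normals at pooled means, so a one-way
ANOVA across classes flags only concreteness and valence. Orthographic
neighbourhood density and length are rounded to nonnegative integers;
prevalence is clamped to [0.98, 1] so every generated word passes the
inclusion filter. Words are resampled (bounded retries) until they classify
into their intended class; word ids are synthetic labels `w01`–`w32` — real
lexical strings are out of scope.

## Designs

**Triads.** 192 presented trials over 32 words: 168 distinct triads plus 24
exact repeats used for consistency QC. 192 × 3 / 32 = 18, so exact per-word
balance is enforced over *presented* trials (168 distinct triads alone
cannot be balanced: 504/32 is not an integer; the repeats are chosen to
complete the balance). Construction is staged: (1) randomized greedy
sampling of distinct triads that keeps per-word counts level and respects a
per-pair cap of 6 triads; (2) a hill-climb selection of the 24 triads to
repeat so each word's presented count is exactly 18; (3) a 2-opt pass that
re-partitions two triads' six words to reduce the number of pairs occurring
in only one triad — such pairs make similarity estimates hostage to the
third word shown. The pass is greedy with a fixed budget (10,000 moves);
exact minimization is not attempted, and typical runs end with ~5–10
singleton pairs. All constraints are re-checkable via `design_stats`.

**Pairs.** 256 unique pairs with every word in exactly 16, by explicit
regular-graph construction: a circulant 4-regular graph within each
quadrant (16 pairs × 4 classes), stacked random matchings for each
quadrant pairing sharing one dimension (32 × 4) and sharing none (32 × 2).
Each pair is presented twice per task with opposite instructions
(concrete/abstract or positive/negative, polarity order randomized), packed
into 16 blocks of 32 by randomized greedy assignment under the
no-repeated-pair and ≤ 5-occurrences-per-word block constraints; both tasks
share the block structure. Per-participant presentation order shuffles
blocks and trials within blocks (pairs), or the whole trial list with
repeats kept non-adjacent to their originals (triads).

## Response simulation

Group-level latent spaces are linear maps of the z-scored norms,
coords = Z·Wᵀ + N(0, σ²), min–max rescaled to the unit square (the support
of the inference prior). Presets: control-like W loads dimension 1 as
0.7·concreteness + 0.6·valence and dimension 2 as 0.7·dominance −
0.5·arousal; SV-like W loads −0.9·valence and 0.6·valence on the two
dimensions (a valence-only, effectively one-dimensional organization);
σ = 0.3 in both. The signs and sparsity mirror the qualitative structure the
analysis should recover; no published coefficient magnitudes are claimed.

Triad responses follow the same exponential-decay rule the inference model
assumes, with per-participant determinism δ drawn log-normally (median 3
for control-like, 1.5 for SV-like, log-SD 0.3) so SV-like data are noisier
and produce wider posteriors. Pairwise responses use a logistic comparator:
P(choose left | "concrete") = logistic(κ_conc · (z_left − z_right)) on the
z-scored attribute, sign-flipped for the negative-pole instruction; κ
medians are 3 for both attributes in control-like responders and 0.3
(concreteness) vs 3 (valence) in SV-like responders. The tasks themselves
imply no particular response model; the logistic form is a generator-side
convention. A lapse parameter (0.02 / 0.05) mixes in uniform guessing.
Everything is reproducible from a single cohort seed, and the generator
returns the ground-truth configurations and profiles for recovery tests.

What the generator does *not* emulate: reaction times, item-level
idiosyncrasies of real Dutch words, heterogeneous per-patient deficit
profiles, or session effects. Passing recovery tests therefore shows the
pipeline is correct and well calibrated under its own assumptions — not
that real patient data will be this clean.

## Bayesian MDS

Uniform prior on [0, 1]² per word; Gamma(2, 1) prior on each δ; likelihood
as above with Minkowski exponent r (default 2, configurable ≥ 1; only 2
latent dimensions are supported). The sampler is random-walk
Metropolis-within-Gibbs: per-word 2D coordinate blocks (Gaussian proposals,
rejected outside the support) and per-participant log-scale δ updates, with
per-block step sizes adapted toward ~0.3 acceptance during warmup only.
Chains initialize from classical (Torgerson) scaling of an empirical
dissimilarity — 1 minus the fraction of co-occurring trials in which a pair
was implicitly chosen as most similar — which removes most burn-in at
negligible cost; `init="random"` is available. Full-scale defaults are
2,000 warmup and 5,000 post-warmup sweeps; 50 draws are retained at even
thinning, enough to propagate configuration uncertainty through the
regressions and randomness statistics. Tests and the recovery experiments
use 400/1,000 sweeps with 10–20 pooled participants (a few seconds per
fit); at that scale distance-matrix recovery correlation is ~0.85–0.9.

The likelihood is invariant to rotation, reflection and translation, so
coordinates are non-identifiable: convergence is diagnosed on pairwise
distances (split-chain R-hat over a subset of pairs, threshold 1.1,
recorded as a warning, never fatal), and retained samples are aligned by
rigid Procrustes (translation + rotation/reflection, no scaling — distances
are preserved exactly) to an iterated mean template. For comparisons
against a *known* space (simulated data), samples are aligned to that
reference instead: without an external reference, per-dimension statements
("dimension 1 is driven by concreteness") are not well posed. The
posterior-mean configuration is only defined after alignment, and the
per-sample regression machinery refuses unaligned input.

## Dimension interpretation

Each dimension is regressed (OLS with intercept) on eight norms —
concreteness, valence, arousal, dominance, AoA, OND, length, prevalence
(frequency serves as an inclusion filter, not a predictor). Predictors are
z-scored by default so coefficients are comparable across fits; a raw-scale
option exists and leaves t-values unchanged. Significance is two-tailed
|t| > 1.96 with no multiple-testing correction, both on the posterior mean
and per retained sample (reported as the fraction of samples significant).
A rank-deficient predictor matrix is an error naming the collinear columns;
fits with fewer than 10 words are refused. Under pure-noise outcomes the
per-predictor rejection rate is calibrated (0.03–0.07 at nominal 0.05 over
1,000 replicates — the test uses the exact-t critical value for n = 32).

## Spatial randomness

R = (mean nearest-neighbour Minkowski distance of the configuration) /
(the same statistic averaged over n_random uniform reference
configurations; default 10,000, reducible — it only affects the Monte-Carlo
error of the denominator). By default the reference is drawn on the
configuration's axis-aligned bounding box, which makes R invariant to
translation and scaling when no generating support is known. Note a
finite-sample subtlety: for n = 32 points the sample bounding box is
conditioned on the extremes, which inflates R to ~1.08 for genuinely
uniform configurations. When the generating support *is* known (calibration
studies, prior samples), pass it explicitly via `support=`; R for uniform
configurations then averages 1.00 (±0.03 over 100 replicates). A degenerate
configuration (all points identical) returns R = 0 with a warning. Group
comparisons use the two-sample Kolmogorov–Smirnov test on the per-sample R
distributions.

In the synthetic study, posterior smearing pulls each group's R toward 1
relative to its generating configuration, and more strongly for the noisier
SV-like group — the mechanism by which impaired, high-uncertainty
responders yield spatially more random fitted spaces.

## Pairwise scales and single-case statistics

A word scores +1 per trial in which it is chosen under the positive-pole
instruction, −1 under the negative pole, 0 otherwise; the sum is divided by
the word's *unique-pair* count (16), not its trial count (32), so a fully
consistent extreme word attains ±1. Unchosen words contribute 0 to their
own totals. Agreement with the generating norms uses Kendall tau-b (ties
are certain at 1/16 score resolution). Single cases are compared with the
control sample by the Crawford–Howell modified t-test,
t = (x − m)/(s·√((n+1)/n)) with n − 1 df, two-tailed by default; zero
control variance is reported as an infinite t with a flag rather than an
error. The (valence, concreteness) scale space is mapped onto the rating
space by similarity Procrustes: both configurations column-centred and
scaled to unit Frobenius norm (a global, not per-column, scale — this keeps
the SS error invariant under any similarity transform of either input),
then the SVD-optimal rotation/reflection and isotropic scale. Per-stimulus
squared residuals sum to the SS error and feed a one-way ANOVA across the
four word classes.

## Consistency QC

Triad consistency: fraction of the 24 repeated triads answered with the
same odd word (chance 1/3); pairwise consistency: fraction of pairs whose
choices under opposite instructions differ (chance 1/2). Missing halves are
dropped from the denominator with a warning. Reaction-time screening is out
of scope (no RTs are simulated).

## Pipeline and determinism

`run_study` derives every stage seed from one study seed via a single
generator, so full runs are byte-identical across processes (set iteration
over hashed strings is avoided everywhere order matters). Outputs are CSV
(floats written at %.17g and read with round-trip precision) and JSON,
including a run log with per-stage timing and a config digest. Default
cohort sizes are 77 control-like and 10 SV-like participants;
`reduced_study_config()` provides a smoke-scale variant (5 + 2 participants,
short chains) that completes in well under a minute.

## Known limitations

- The sampler is adequate at 32 words × 2 dimensions but is not
  gradient-based; much larger stimulus sets would need HMC or variational
  inference.
- The block-assignment and triad searches are randomized-greedy with
  restarts: they satisfy the printed constraints but make no optimality
  claim (singleton-pair counts reach "few", not the minimum).
- Kendall correlations of real participants depend on response strategies
  the logistic comparator does not model (anchoring, drift); simulated tau
  values should not be read as predictions of empirical ones.
- R's bounding-box null is a pragmatic default; analyses that care about
  absolute R levels should fix the support explicitly.
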