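# Methods

## Task geometry

The arena is a circle of radius R = 25 virtual meters (vm) centered at the
origin, with an intra-arena landmark at (−10.5, 10.5) and four objects at
fixed coordinates: cat (−5, −14), chair (−4, 20), bike (18, 10), carrot
(5, 17). Participants start at the center. Two partitions support the
density analyses:

* **radial** — inner disk of radius 12.5 vm (boundary included) vs the
  outer annulus; the inner disk holds exactly 25% of the arena's area, so
  the binomial null for an inner count is p₀ = 0.25;
* **quadrant pair** — the open upper-left quadrant (x < 0, y > 0, which
  contains the landmark) vs the open lower-right quadrant; equal areas,
  null p₀ = 0.5. Points on the axes belong to neither quadrant and are
  excluded from the pair count (a measure-zero set for continuous data;
  excluding them avoids double counting). Out-of-arena points, which can
  only arise from malformed input, are never silently dropped: every
  density report carries `n_excluded`.

## Per-trial recall measures

* **Error**: Euclidean distance between the response and the cued object's
  encoded location, in vm.
* **Attractor indices**: for a reference point R (landmark or center),
  `(d_target − d_response)/d_target`, where `d_target` is the
  target-to-reference distance and `d_response` the response-to-reference
  distance. The normalization is by `d_target`, not by the arena radius, so
  the index is comparable across objects at different distances from the
  reference. By this formula the index is +1 on the reference point, 0 at
  the target, and negative for responses farther from the reference than
  the target is — positive values therefore mean displacement *toward* the
  reference. (Prose descriptions of the center index sometimes swap the
  sign labels; the formula as implemented is the self-consistent reading,
  and the group contrasts it produces match the reported direction.)
* **Binding errors**: a trial is a binding error when the encoded object
  location nearest to the response is not the cued object's — the
  object-place swap notion. A strict minimum is used; exact ties are
  counted as binding errors and flagged ambiguous. No distance cap is
  applied by default (a far response still has a nearest object); an
  optional capture radius can restrict flags to responses near the wrong
  object.
* **Switch labels**: trial *t* ≥ 2 is labelled by the cue transition from
  trial *t* − 1 (`no_switch`, `ego_to_allo`, `allo_to_ego`); trial 1 is
  `first_trial` and is excluded from switching analyses. Presentation
  order is taken from the recorded trial indices.

## Density statistics

Counts are pooled across participants within a group (the group-level
analysis the published percentages correspond to); a per-participant
variant is available through `summarize_paths`/per-session scoring for
sensitivity checks. Densities are counts divided by region areas; the
density ratio is inner/outer (radial) or upper-left/lower-right
(quadrants). For equal-area quadrants the density ratio equals the raw
count ratio. Group contrasts report both the difference and the ratio of
the two groups' density ratios. The exact binomial test is two-sided by
the minimum-likelihood rule (sum the null probabilities of all outcomes no
more likely than the one observed), the convention that reproduces the
published p-values. Note the pooled test treats path samples as
independent although consecutive 1 Hz samples are autocorrelated; this
follows the published procedure and is a known caveat, not a bug.

## Inferential layer

The error model is a linear mixed model with fixed effects group, cue and
their interaction (Sum-coded, type-III tests) and a random intercept per
participant, fit by REML (statsmodels MixedLM). F-tests follow the
split-plot decomposition: between-participant terms are tested by OLS in
the participant-mean stratum with denominator df `n_participants −
p_between` (for 80 participants and a two-level group factor: F(1, 78));
within-participant terms use Wald statistics from the mixed fit with
containment df `n_obs − n_participants − p_within`. The between-stratum
test is used because the trial-level Wald covariance understates
between-participant uncertainty whenever the random-intercept variance
estimate hits the REML boundary at zero — with the split-plot test the
null distribution of the group p-value is uniform (verified by simulation
in the acceptance suite). Cohen's f is computed as `√(F·df₁/df₂)`.

The trial-order model adds orthogonal polynomial terms in trial index
(degree 2 by default, configurable; degree 0 reduces exactly to the plain
ANOVA) and their interactions with group and cue. Attractor indices are
modelled with group as fixed effect and crossed random effects for
participants and objects (variance components); the group F again comes
from the participant-mean stratum. Binding counts per participant × cue
use Poisson regression. The diagnosis model is a logistic regression with
aMCI coded 1, per-participant predictors (cue means or switch-condition
means of trial error, unstandardized so odds ratios are per-vm), Wald
standard errors, OR = exp(β) with 95% Wald CIs, and an optional
ridge-penalized fallback for separated data (always flagged in the result
notes). Covariate adjustment accepts extra column names (patsy product
terms such as `age:gender` are passed through raw and uncentered). No
multiple-testing correction is applied; all p-values are reported raw.

ROC analysis uses the rank/concordance AUC (midranks; tied pairs receive
half credit) — equivalent to the trapezoidal area. Candidate cutoffs are
midpoints between adjacent distinct scores plus outer sentinels; a case is
called positive when its score ≥ cutoff. The operating point maximizes
Youden's J = sensitivity + specificity − 1; among tied maxima the smallest
cutoff is returned, with a tie flag.

## Synthetic cohort model

The simulator is phenomenological — a drift + noise walk and a
shrink-toward-attractor response model — not a cognitive model. It
emulates the *group-level behavioral signatures* of the task: it does not
model vestibular/embodied cues, learning within the session, fatigue, or
individual strategy switching, so passing recovery tests demonstrates that
the pipeline detects the built-in signatures at realistic effect sizes,
not that the phenotypes exhaust real aMCI behaviour.

**Encoding.** Per 1 Hz step the heading is the unit vector toward the
current target plus `thigmotaxis_weight` × the outward radial unit vector
plus `landmark_approach_weight` × the unit vector toward the landmark,
perturbed by Gaussian heading noise (SD `heading_noise_sd` radians); step
length is `step_speed` (0.9 vm/s) and positions are clipped radially to
the arena (the invisible wall). The combined drift tapers linearly within
5 vm of the target and is capped at 0.85 of the goal vector so every
target remains reachable even under extreme drift weights; captures occur
within `capture_radius` (1 vm — exact contact is measure-zero for a noisy
walk), after which the final approach snaps onto the object location,
mirroring the task rule that objects are collected by walking over them.
The 16-item schedule covers each object 4 times in random order.
Encoding time is `n_samples/60` minutes. A step cap (default 20 000)
raises a simulation error with diagnostics rather than looping forever.

**Recall.** Responses are `target + a·(attractor − target) + N(0, s²I)`,
clipped to the arena, with `a = center_attraction` toward the center on
allocentric (boundary-cue) trials and `a = landmark_attraction` toward the
landmark on egocentric (landmark-cue) trials. The 16-trial order is a
random interleaving satisfying two-per-object-per-cue. Response time is a
nuisance covariate only: straight-walk travel time plus lognormal jitter.
Per-participant heterogeneity enters as a lognormal multiplier (sigma
`participant_variability`) on the response noise scale; an
`egocentric_noise_scale` multiplier is available for cue-specific
precision manipulations (1.0 in both default phenotypes).

**Default phenotypes.** Controls: moderate outward drift (0.35), mild
landmark approach (+0.10), response noise SD 30.5 vm, weak attractions
(0.08). aMCI: stronger outward drift (0.50), landmark avoidance (−0.08),
more heading noise, response noise SD 30.0 vm, strong attraction to the
center (0.45) and the landmark (0.70). The noise scales were calibrated
once, by Monte Carlo at 200 participants per group, so that group mean
recall errors land near 21.3 vm (controls) and 23.9 vm (aMCI). At these
error magnitudes — close to the ceiling a clipped response distribution
allows in a 25 vm arena — extra isotropic noise can barely separate the
groups, so the aMCI error surplus is carried almost entirely by the
systematic attraction toward the cue anchors. That choice is deliberate:
it makes the groups differ *qualitatively* (response distributions pulled
toward landmark/center, centrifugal encoding paths) more than
quantitatively, which is exactly the signature structure the phenotypes
are meant to express, and it makes the egocentric error — inflated by the
strong landmark attraction — the discriminating predictor. Between-
participant variability is set to 0.10, giving participant-level error
SDs near 3 vm and a group effect size around f ≈ 0.4.

**Determinism.** All randomness flows from a single spec seed;
per-participant seeds are `crc32(f"{seed}:{group}:{index}") mod 2³¹` and
are recorded in the manifest, so cohorts are reproducible file-for-file.

## Numerical and interface choices

* Welch's t wraps `scipy.stats.ttest_ind(equal_var=False)` with explicit
  guards (≥ 2 values per sample, non-degenerate variance); the exact
  binomial test wraps `scipy.stats.binomtest`, whose two-sided method is
  the minimum-likelihood rule.
* Path metrics are defined per sample, matching the task's 1 Hz design;
  irregular time stamps are accepted with a warning. Sessions with missing
  path files are skipped by path analyses, and the n actually used is
  reported. The mean-distance metrics include the first sample (the start
  point).
* CSV round-trips use pandas with `float_precision="round_trip"` so
  written cohorts reload bit-exactly; pipeline runs are byte-identical
  given the same config.
* In the pipeline, models that cannot be fit on a given cohort (tiny n,
  singular design, separation) are recorded as skipped in the summary
  rather than aborting the run; any other stage failure aborts with the
  stage name and leaves a failure marker beside the partial outputs.
* Problem sizes in the validation suites: recovery checks use 100 cohorts
  of 40 + 40 with full encoding walks; null calibration uses 500
  recall-only cohorts of 40 + 40; oracle-equivalence checks enumerate all
  binomial outcomes at n ≤ 12 and all AUC comparisons at n ≤ 12.

## Known limitations

* The simulator's response model is stationary within a session; it cannot
  express trial-order trends, so the polynomial trial model is validated
  on constructed tables with known slopes instead.
* The pooled binomial density tests inherit the independence caveat above.
* Denominator df for within-participant Wald tests are containment
  approximations, not Satterthwaite/Kenward-Roger; for the balanced
  two-cue design they coincide with the classical split-plot df.
* Robust estimators for unequal-sized subtype comparisons (single- vs
  multiple-domain aMCI) are out of scope; the standard operations accept a
  `subtype` column for subgroup reuse.
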