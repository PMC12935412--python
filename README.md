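# arenanav

Analysis toolkit for object-location spatial-memory tasks in circular
virtual arenas, aimed at researchers studying spatial navigation in aging
and amnestic mild cognitive impairment (aMCI).

In the task this package analyses, participants navigate a circular arena
(50 virtual-meter diameter) containing an environmental boundary (the wall,
an allocentric cue) and a discrete intra-arena landmark (an obelisk, an
egocentric cue). They encode the locations of four objects, then recall
each location under cue conditions in which either the wall or the landmark
has been removed. The toolkit covers the whole analysis chain:

* **recall scoring** — per-trial Euclidean error
  `e = ‖response − target‖`; normalized attractor indices
  `(d_target − d_response)/d_target` toward the landmark and the arena
  center (1 = response on the reference point, 0 = at the target, < 0 =
  displaced away); object-location binding errors (nearest-encoded-location
  swaps); and frame-switching labels (ego→allo, allo→ego, no-switch);
* **trajectory metrics** — step distances, path length, mean distance from
  landmark/center, compared across groups with Welch's *t*;
* **spatial density** — point-pattern counts over an inner-disk/outer-annulus
  partition (25% / 75% of the arena by area) and over the landmark quadrant
  vs its diametric opposite, with area-normalized density ratios and exact
  two-sided binomial tests (minimum-likelihood rule) against the area-based
  null;
* **inferential layer** — split-plot mixed-effects ANOVA (group × cue, random
  participant intercept) with Cohen's `f = √(F·df₁/df₂)`; orthogonal-polynomial
  trial-order models; Poisson regression for binding counts; logistic
  diagnosis models with odds ratios; rank-based ROC with Youden-index
  operating points;
* **synthetic cohorts** — a biased-random-walk simulator with calibrated
  healthy-control and aMCI-like phenotypes (thigmotactic outward drift,
  landmark avoidance at encoding, attraction toward cue anchors at recall),
  so every stage of the pipeline can be exercised and validated without
  access to clinical data.

## Worked example

```python
from arenanav import (ArenaConfig, CohortSpec, simulate_cohort, score_cohort,
                      fit_error_mixed_anova, fit_logistic_diagnosis,
                      participant_cue_means, roc_youden)

arena = ArenaConfig()                       # radius 25 vm, landmark at (−10.5, 10.5)
sessions = simulate_cohort(CohortSpec(n_per_group=40, seed=1, arena=arena))
scores = score_cohort(sessions, arena)      # long table: 80 × 16 trials

g = fit_error_mixed_anova(scores).ftest("group")
print(f"F(1,{g['df_den']:.0f}) = {g['F']:.2f}, p = {g['p']:.4f}, f = {g['f']:.2f}")

cm = participant_cue_means(scores)
logit = fit_logistic_diagnosis(cm, predictors=["error_ego", "error_allo"])
print(logit.term("error_ego")[["estimate", "or_", "p"]].round(3).to_dict())
```

Output:

```
F(1,78) = 14.84, p = 0.0002, f = 0.44
{'estimate': 0.181, 'or_': 1.2, 'p': 0.002}
```

The simulated aMCI group recalls object locations about 2.7 vm less
accurately than controls (group means ≈ 21.0 vs 23.7 vm), the split-plot F
test detects the deficit, and landmark-cued (egocentric) recall error —
not boundary-cued error — predicts group membership (OR 1.20 per vm), the
qualitative signature the default phenotypes are built to express. The
`examples/` directory contains one short script per capability; the
`arenanav` console command (`simulate`, `validate`, `all`) wraps the same
library calls for shell use.

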