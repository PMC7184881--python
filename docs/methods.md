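# Methods

## The dust-competition model

The simulator treats grooming as a competition between noisy sensory drives
from five body parts: head, wings, abdomen, front legs, back legs. The legs
are pooled pairs, each a single competing unit with its own dust entry —
leg rubbing is one behavior per pair, not per leg. State is the dust vector
d(t) ≥ 0; at every iteration each part's drive is an independent normal
draw

    a(t) ~ N(d(t), (d(t)/noise_divisor)²)

with `noise_divisor = 5` by default, i.e. a mean-to-SD ratio of 5 chosen to
match bristle electrophysiology. A part with no dust is exactly silent
(σ = 0 collapses to a point mass at 0). Draws are not truncated at zero:
negative values are admissible because only the argmax matters. Exact ties
at the argmax — which occur only in degenerate configurations such as all
dust zero — are broken uniformly at random, consuming the run's single
random stream so seeded runs stay bit-reproducible.

The winner grooms for one bout, after which dust updates **once per bout**,
not per frame: the removal fraction is defined per grooming bout, and bout
durations are explicitly outside the competition. If the winner is a body
surface, a fraction `dr` of its dust transfers — conserved — to the legs
that clean it (head → front legs; wings and abdomen → back legs, an
anatomy-based assignment); if the winner is a leg pair, it sheds `10·dr` of
its own dust off the fly, the only way dust leaves the system. Hence
`dr ≤ 0.1`. Total dust is non-increasing along any trace, and every entry
stays non-negative by construction (multiplicative updates).

Defaults are the wild-type configuration: initial dust proportional to
bristle counts (head 1200, abdomen 600, wings 400), 200 on each leg pair,
`dr = 0.002` per bout — the value at which simulated progression speed
matches dusted flies, with anterior and posterior probabilities meeting
near the end of a 50,000-frame (27.78 min, 30 Hz) run. The run ends at a
fixed frame horizon, truncating the last bout.

Simulated ethograms contain grooming labels only — the winner set is the
five body parts, so walking and standing are never emitted; the metrics
tolerate records with no non-grooming frames. An optional external-drive
mode replaces d(t) with user-supplied per-part time series as the mean of
a(t) and freezes dust updates, mimicking optogenetic ramp stimulation; it
is an extension beyond the core dust model and no acceptance property
depends on it.

## Bout durations

Durations only render the winner sequence onto the frame axis. The default
is log-normal per behavior: median 2 s for sweeps, 1.5 s for leg rubs,
log-space shape 0.6 — a heavy-tailed law consistent with grooming bout
statistics; the medians and shape are declared configuration, not hidden
constants, and can be replaced wholesale by an empirical sampler that
resamples observed per-behavior frame counts with replacement. Durations
round to whole frames with a floor of 1.

## Quantification

* **Windowed behavior probabilities.** Per fly and window, the fraction of
  frames whose coarse class is anterior grooming (head sweep, front-leg
  rub), posterior grooming (body sweep, wing sweep, back-leg rub), or
  walking. Wing grooming counts as posterior: wing cleaning groups with the
  back-leg movements. Unlabeled/"other" frames count as non-grooming.
  Windows are half-open [t, t+w), start at t = 0, step by the spec's step;
  the final partial window is dropped rather than padded. Presets: 32 s/16 s
  (dust assays), 5 s/2.5 s and 10 s/5 s (optogenetic assays). Cohort curves
  are the across-fly mean with SEM (SD with n−1 denominator over √n).
* **A:P log ratio.** Per fly and non-overlapping bin (150 s default; 120 s
  and 60 s for stimulation-style analyses), `log10((F_A+1)/(F_P+1))` with
  anterior/posterior frame counts; the +1 offsets keep all-one-pole bins
  finite, and a fly-bin with no grooming at all is excluded from summaries
  rather than scored — a fly that walked through a bin carries no
  information about its grooming preference.
* **Anterior half-time.** First time the cumulative anterior frame count
  reaches ⌈total/2⌉, in seconds; the denominator is the analyzed record
  (optionally a stated time range, e.g. a stimulation epoch). Undefined —
  an error — when the record has no anterior frames.
* **Crossover.** First window whose cohort-mean posterior probability
  reaches the anterior probability, on unsmoothed means (no filtering
  beyond the windowing itself).
* **Group comparisons.** Wilcoxon signed-rank (paired), Wilcoxon rank-sum
  (independent; the normal-approximation `scipy.stats.ranksums`),
  Kruskal–Wallis with pairwise rank-sum post hoc for ≥3 groups. No
  multiple-testing correction is applied by default, matching standard
  practice for these assays; a Bonferroni flag exists. Identical paired
  samples (all-zero differences) report p = 1 — no evidence of a shift —
  rather than erroring.

## Synthetic ethograms

The generator emulates classifier output for dusted flies — 30 Hz label
streams of ~50,000 frames, cohorts of ≥10 flies — without any dust
dynamics, so metric behavior can be validated against known ground truth. It
is semi-Markov: each bout draws a class (grooming with probability
`grooming_fraction`, default 0.9 since dusted flies groom most of the
record; otherwise walk/stand equally), grooming bouts draw anterior vs
posterior from `anterior_bias(t)` evaluated at bout start, and a duration
from the bout model. Within a run of same-pole grooming bouts the label
alternates sweep ↔ rub with probability 0.8 (configurable), mimicking the
sweep/leg-rub cycling of real grooming; posterior sweeps split evenly
between body and wing sweeps. The logistic preset
`1/(1+exp(k(t−t0)))` crosses 0.5 at t₀, so the cohort crossover time should
recover t₀ — the generator-recovery property the tests enforce.

What the generator does not emulate: within-fly autocorrelation beyond bout
alternation, classifier label noise, inter-fly heterogeneity in bias or
tempo, and any coupling between behavior and dust. Passing metrics tests on
synthetic cohorts therefore demonstrates correctness of the computations,
not robustness to real-data artifacts.

## Numerical and testing choices

* All randomness flows from one `numpy` Generator per run; cohorts derive
  per-fly seeds from a `SeedSequence` on the base seed (kept below 2³¹).
* Stochastic checks use frozen seeds and tolerances derived from
  independent oracles: winner frequencies are compared against a
  brute-force vectorized normal-argmax Monte-Carlo oracle (and, for
  two-part competition, the closed form Φ(Δd/√(σ₁²+σ₂²))) with two-sided
  binomial tests; the balanced-bias window check uses a per-window bound of
  0.12 frozen from a Monte-Carlo oracle of duration-weighted window
  fractions — heavy-tailed bouts leave far fewer effective draws per 32 s
  window than the frame count suggests, so cohort means of 20 flies wander
  up to ~0.10 from the nominal 0.5 in individual windows.
* Conservation properties are asserted on fresh random dust states per
  iteration; chaining 10⁵ multiplicative decays onto one state underflows
  into denormals where "strict decrease" stops being a statement about the
  model.
* Cohort-scale checks run at the study's stated sizes (10–20 flies, 50,000
  frames, 10-seed replicates); the simulator is bout-level, so a full run
  is a few hundred updates and the whole suite completes in well under a
  minute. The CLI smoke test scales `reproduce-figures` down to 3 flies ×
  20,000 frames; the real command defaults to 10 × 50,000.

## Known limitations

The model deliberately omits suppression hierarchies between behaviors,
spatial targeting of individual bristles, and neural-circuit dynamics; it
also cannot produce walking, so simulated walk curves are identically zero.
Whether wings transfer dust to the back legs alone is an anatomy-based
choice, not a measured fact. The ABRS classifier's exact label vocabulary
is broader than the eight tokens used here; the reader's alias table maps
any richer vocabulary onto them.
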