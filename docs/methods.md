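# Methods

`partikel` re-implements, as a tested pipeline over synthetic data, the
computational machinery of a 2x2 reading experiment on German verb-particle
dependencies: quantifying particle predictability from cloze norms, deriving
locality predictions from an activation-decay simulator, computing
eye-movement reading measures, and fitting Bayesian hierarchical reading-time
models compared by Bayes factors.  This note records the models, the defaults,
and the design choices made where the procedure was genuinely open.

## Cloze statistics

For each item x condition the cloze probability of a completion is its
respondent proportion, and particle predictability is summarized by the
Shannon entropy of the completion distribution in bits,
`H = -sum_i P_i log2 P_i` (terms with `P_i = 0` contribute 0).  By default the
probability universe is restricted to completions flagged as particles; a flag
retains non-particle completions for sensitivity checks.  Completion strings
are normalized by trimming, lowercasing, and keeping the first token.

Condition summaries fit a Beta distribution to per-item target-cloze values by
method of moments (with mean m and variance v, `nu = m(1-m)/v - 1`,
`a = m nu`, `b = (1-m) nu`) and report its mean and 2.5%/97.5% quantiles.  No
distributional form suggests itself for entropies, so their interval is a
nonparametric bootstrap (2,000 resamples, seeded).  Both are across-item
summaries; across-respondent summaries can be built from the raw tables.
Median splits label values strictly above the median "high" and everything
else — including ties at the median — "low", a deterministic convention.

Item selection retains an item only if every condition elicited at least one
particle and, within each distance level, the large-set condition elicited
strictly more particle types than the small-set condition.

## Decay simulator

The simulator isolates temporal decay: all plausible particles share a finite
pool of spreading activation W, so each of n candidates starts at W/n;
base-level activation decays as a power function of the elapsed time t; and
retrieval latency is exponential in activation at retrieval:

    A(n, t) = ln(t^-d) + W/n,        T(n, t) = F exp(-A) = F t^d exp(-W/n).

Defaults: d = 0.5 (the conventional decay exponent of activation-based memory
models), W = 1 activation unit, F = 200 ms, with the distance manipulation
mapped to seconds as `t = t0 + k * words` (t0 = 0.4 s, k = 0.4 s/word, a
typical per-word reading time).  Only the relative 2x2 pattern is contractual
— small-set cells are always faster, and the distance (locality) cost
`F e^(-W/n) (t_long^d - t_short^d)` strictly grows with n, producing the
crossing interaction.  Absolute milliseconds depend on F and W and are not
calibrated to data.  Optional Gaussian activation noise makes cell means
averages over seeded replicates; interference, cue overlap, and any full
retrieval-race machinery are deliberately out of scope.

## Eye-movement measures

Measures are computed for the merged span of the particle and the word to its
left (two-to-three-letter particles are frequently skipped).  First fixation
duration, first-pass reading time, total fixation time, and regression path
duration (go-past) follow the standard definitions; two conventions required a
decision because the verbal definitions are silent:

* if material to the right of the region is fixated before the region is ever
  entered, the region counts as skipped in first pass (FFD/FPRT/RPD missing,
  TFT may still accrue);
* if no fixation ever lands right of the region, RPD runs to the end of the
  trial and is flagged `rpd_unterminated`;
* a first-pass fixation on the pre-particle word alone counts as fixating the
  merged region (merged-span semantics).

Zero- and negative-duration fixations are rejected at parse time.  Trials
flagged for blinks or track loss are excluded before any measure computation,
with counts logged.

## Synthetic data

The generator reproduces the statistical structure the analyses assume, not
sentence content: items are abstract ids with condition labels and entropy
values.  Defaults are the study conditions: 60 participants x 24 items in a
four-list Latin square (6 trials per condition per participant) with 72
fillers; the norming study uses 48 items, 63 fillers (111 sentences per list)
and ~31 respondents per item x condition (126 split over four lists).

Self-paced reading times are reciprocal-normal: speed (words/s) is Gaussian on
the transformed scale with crossed participant/item random effects, and
`rt = 1000/speed`.  Generating fixed effects default to the magnitudes the
experiments were designed around (intercept 2.5 words/s; condition effects of
a few hundredths of a word/s on +-0.5 codes).  Speeds below 0.1 words/s are
resampled, and a configurable 1% of trials is replaced by uniform 30-99 ms
presses so the < 100 ms exclusion rule is exercised.  Comprehension accuracy
is Bernoulli at 0.94 with lognormal ~2 s question latencies; accuracy is
reported but never used as a filter.

Eye-tracking measures are built compositionally to guarantee the containment
invariants: FFD is lognormal (log-scale intercept 5.66 ~ 287 ms, residual SD
0.25); FPRT adds a refixation increment with probability 0.15; TFT adds
re-reading (0.25) and RPD a regression increment (0.20), each lognormal.
Four correlated lognormals would not guarantee FFD <= FPRT <= TFT and
FPRT <= RPD row-wise; the compositional scheme does.  The generator can also
emit full fixation sequences arranged so that recomputing measures from them
reproduces the stored values exactly, giving an end-to-end oracle for the
measure module.  Blink flags are planted at 5%.

Per-item entropies come from two overlapping Gaussian components (small-set
mean 1.10 bits, large-set mean 1.20, common SD 0.35, truncated at 0) so both
set-size categories contain high- and low-entropy items — the configuration
that motivates treating entropy as a continuous predictor.  Cloze completions
are multinomial over a small (4) or large (12) particle inventory with
Dirichlet-distributed probabilities; the symmetric concentration controls
entropy, non-particle completions occur at a configurable rate, and a
configurable 8% of items designate a non-modal target (the rule by which such
targets arise in stimulus construction is not recoverable, so it is a rate,
not a rule).

What the generator does not emulate: word-position effects along the
sentence, spillover, sentence wrap-up, frequency effects, skipping of the
merged region (first-pass skips arise only in hand-built test sequences), or
any dependence of accuracy on condition.  Passing tests therefore certify the
statistical machinery, not conclusions about real readers.

## Hierarchical reading-time models

The analysis model is a Gaussian linear mixed model on a transformed response
— `1000/rt` (words/s) for self-paced reading, `log rt` for each eye-tracking
measure, in both cases the transform indicated by the Box-Cox profile
likelihood (grid [-2, 2], step 0.1) — with +-0.5 effect codes and crossed
participant/item random effects.  Priors (self-paced / eye-tracking):

    intercept  ~ Normal(3, 0.5)   /  Normal(5.7, 0.5)
    slopes     ~ Normal(0, 0.5)
    RE SDs     ~ Normal+(0, 0.25) /  Normal+(0, 1)
    residual   ~ Normal+(0, 0.25) /  Normal+(0, 1)

so that 95% of prior reading speeds fall in 2-4 words/s and 95% of prior
durations in 110-812 ms (the half-up roundings of exp(5.7 +- 1)).

Because all random effects are Gaussian, they are integrated out analytically:
the marginal covariance `V = sigma^2 I + Z G Z'` is handled with the Woodbury
identity on cross-products (`X'X`, `Z'Z`, `Z'X`, `Z'y`) precomputed once per
dataset, so a likelihood evaluation costs O(k^3) in the number of random-effect
columns and nothing in the number of trials.  The resulting marginal posterior
(fixed effects, random-effect SDs, residual SD; SDs sampled on the log scale
with the Jacobian) is low-dimensional and is sampled with an affine-invariant
ensemble sampler using differential-evolution moves (48 walkers by default,
600 warmup + 600 retained steps, thinned by 2).  Walkers are grouped into four
pseudo-chains for split-Rhat and effective-sample-size diagnostics; a fit with
max split-Rhat >= 1.01 is flagged and refused by the Bayes-factor stage.

`random_structure` selects by-participant and by-item random intercepts (the
default), intercepts plus independent random slopes for every fixed effect, or
no random effects (used by the conjugate oracle tests).  Random-effect
*correlations* are fixed at zero in the sampler: the LKJ(2) prior that the
full-covariance formulation would place on them concentrates mass near zero,
none of the reported quantities involve the correlations, and marginalizing a
correlated G adds a per-evaluation cost with no tested benefit.  The
`PriorSpec.lkj_eta` field records the intended concentration for transparency.

The entropy analysis replaces the set-size code with mean-centred continuous
entropy (centring is the default and changes only the intercept's meaning; a
flag disables it).  Self-paced trials under 100 ms are excluded before
fitting; eye-tracking trials with a skipped region drop out via missing
responses, with counts logged.

The cloze probability model is a zero/one-inflated Beta regression —
`p(0) = alpha(1-gamma1)`, `p(1) = alpha gamma1`, continuous part
`(1-alpha) Beta(mu phi, (1-mu) phi)` with logit-linear `mu` — with the
regularizing Normal(0, 0.25) slope prior.  The entropy model is a
hurdle-lognormal — `p(0) = theta0`, positive part lognormal with a linear
location — with the Normal(0, 0.01) slope prior implemented as stated; this
prior shrinks slopes essentially to zero, which the test suite documents as
behaviour, and a `slope_scale` argument exposes the sensitivity check.
Both likelihoods are verified to integrate to one by quadrature.

## Bayes factors

BF10 for a predictor compares the full model against a reduced model without
that fixed effect, at three slope-prior widths: Normal(0, 0.1) (informative),
Normal(0, 0.5) (planned), Normal(0, 1) (diffuse).  When random slopes are
estimated, the reduced model retains the dropped predictor's random slopes so
the comparison concerns the population-level effect only.  Marginal
likelihoods are estimated by iterative optimal bridge sampling (moment-matched
Gaussian proposal, tolerance 1e-6, at most 1,000 iterations) from the
marginal-posterior draws; the estimate is the mean of three disjoint-batch
repeats and the reported error their spread, with a warning above 0.5 nats.
The estimator is validated against a conjugate-Normal closed form before any
pipeline use.  Evidence labels use the conventional graded scheme with
working thresholds 3.0 and 0.3.  Bayes factors are reported per measure with
no correction for multiplicity, and the report says so.

## Pipeline

`run_pipeline` executes simulate -> cloze -> measures -> decay predictions ->
fits -> Bayes factors -> report.  Every stage seed is a fixed function of one
master seed, so identical configurations produce byte-identical CSV tables.
Condition summaries report the mean and a bootstrap 95% CI over
by-participant means (2,000 resamples).  Exclusion accounting asserts
`trials_in = trials_retained + sum(trials_excluded by reason)` on every run.
The YAML config round-trips exactly.

## Problem sizes and numerical choices

Test fits run at the full 60 x 24 design (1,440 trials) with reduced sampler
budgets (400-500 warmup/retained steps), which the diagnostics accept for the
intercepts-only structure; parameter-recovery calibration uses 20 simulated
experiments per response scale and checks that generating fixed effects fall
in their 95% credible intervals in at least 90% of checks, pooled over the
four fixed effects.  Recovery simulations generate with random intercepts
only, matching the fitted structure, because the property under test is
sampler calibration; the generator's defaults keep nonzero slope SDs.
Degenerate inputs fail loudly: single-participant or single-item data,
non-positive responses in Box-Cox, zero-variance summaries (point CI plus a
warning), indivisible item counts, and probabilities outside [0, 1] all raise
typed errors.

## Known limitations

* Random-effect correlations are not estimated (see above); fits with
  `random_structure="slopes"` estimate independent slope SDs only.
* The marginalized sampler reports random-effect SDs, not the individual
  participant/item adjustments; conditional (BLUP-style) adjustments can be
  derived from the draws but are not part of the summary tables.
* The ensemble sampler's pseudo-chain split-Rhat is conservative but not
  identical to independent-chain Rhat; thresholds were chosen accordingly.
* Entropy intervals and condition-summary CIs are bootstrap percentile
  intervals; with fewer than ~10 items per level they are optimistic.
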