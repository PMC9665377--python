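# Methods

## The model

`trisense` implements a two-level Bayesian causal inference model of the
full-body ownership illusion under combined visuo-tactile (VT) and
visuo-vestibular (VV) stimulation, together with a synthetic-data
generator for the 2×2 synchrony design and the statistical pipeline
used to analyze such studies.

### Pairwise causal inference

During a trial the participant watches a mannequin body from the
first-person perspective while receiving strokes (paired with a visible
ball touching the body, 0.5 Hz) and galvanic vestibular pulses (paired
with visible body rotation, one per 7 s).  Each paired event yields a
measured onset disparity between the visual event and its tactile or
vestibular partner.  Measurement noise is Gaussian: a disparity for the
VT pair has SD `sqrt(sigma_v^2 + sigma_t^2)` around the true lag (0 s
when synchronous; 1 s tactile / 2 s vestibular lag when asynchronous).

For one event with disparity `x`, the posterior probability of a common
cause is Bayes' rule over two Gaussian hypotheses,

    P(C=1 | x) = p L1(x) / (p L1(x) + (1-p) L2(x)),

where `L1 = N(x; 0, sigma_a^2 + sigma_b^2)` (common cause) and
`L2 = N(x; 0, sigma_a^2 + sigma_b^2 + 2 sigma_indep^2)` (independent
causes, whose true onsets are themselves dispersed with SD
`sigma_indep` each), and `p` is the prior probability of a common
cause for that pair.

Event-level posteriors are pooled on the log-odds scale — the pairwise
estimate `d_pair` is the logistic of the mean logit — and the pairwise
reliability is

    w_pair = K / (sigma_a^2 + sigma_b^2),

with `K` the number of events.  Fisher information adds over
independent events, so the pair sampled more often (90 strokes vs 25
pulses in a 3-minute trial) carries proportionally more weight.  This
event-count scaling, the Gaussian likelihoods, and the logit-mean
pooling are this package's concrete instantiation of the verbal model;
each lives behind its own function so alternatives can be swapped.

### Ownership and feedback

The overall ownership estimate is the reliability-weighted average
(model averaging across the two bimodal pathways):

    d_own = (w_VT d_VT + w_VV d_VV) / (w_VT + w_VV).

The emerging percept feeds back onto the bisensory priors on the
log-odds scale, `logit(p_i) = logit(p_i0) + w_i * gamma * (2 d_own - 1)`,
clipped to [0.01, 0.99] to avoid absorbing states.  The loop is solved
as a damped fixed point (damping 0.5, tolerance 1e-6, cap 100
iterations); convergence and damping-independence are tested
properties, not assumptions.  Feedback is implemented within-trial; the
alternative readings (across trials or sessions) are observationally
similar here because analytic predictions use the fixed point anyway.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `sigma_v` | 0.05 s | visual onset noise |
| `sigma_t` | 0.08 s | tactile onset noise |
| `sigma_vest` | 0.45 s | vestibular onset noise (GVS is vague in onset) |
| `sigma_indep` | 1.0 s | onset-disparity prior under independent causes |
| `p_vt0`, `p_vv0` | 0.5 | baseline common-cause priors |
| `w_prior_*` | 0.5 | feedback weight per pair |
| `gamma` | 1.0 | feedback gain (log-odds per unit ownership) |

This profile puts the model in the `w_VV << w_VT` regime (weight ratio
~80:1): the four-condition ownership table is ~0.958 / 0.948 / 0.008 /
0.000 for SVV_SVT / AVV_SVT / SVV_AVT / AVV_AVT, reproducing the
study's signature — tactile asynchrony breaks the illusion, vestibular
asynchrony barely dents it, and the fully synchronous and
tactile-synchronous conditions are near-equal.

Self-motion is a linear readout `m = b0 + b_vv [vv_sync] + b_vis d_own`
(defaults 0.5 / 0.90 / 1.0, with `b_vv` calibrated once so the two
mixed conditions predict near-equal self-motion, matching their
observed equivalence on the VAS).

## The synthetic-data generator

`draw_profiles` samples participants from population distributions:
log-normal sensory noises (the vestibular SD has sdlog 0.6, CV ≈ 0.66 —
this wide spread is what produces the between-participant variation in
vestibular reliability behind the difference-score correlation), Beta
priors (mean 0.5, concentration 16), and Gaussian response-linking
parameters.

Questionnaire responses use a cumulative-logit link: the latent for S1
is `intercept + slope * logit(d_own) + random_intercept`, S2/S3 use the
post-feedback pairwise posteriors, S4/S5 sit below the lowest cutpoint
(controls are rejected), S6 is condition-independent, and S7 maps the
self-motion readout onto the 0–10 VAS with Gaussian noise and clipping.
Adding logistic noise and binning by the participant's six cutpoints
makes the generator the exact inverse of the fitted cumulative link
mixed model, which is what makes clean parameter-recovery tests
possible.  The participant-level offset SD is 1.5 on the logit scale;
with logistic response noise (variance π²/3) a smaller spread would not
reproduce the strong positive correlation between ratings in the two
synchronous-vestibular conditions that real cohorts show.

SCR trials follow
`raw = baseline * exp(-attenuation (r-1)) * (1 + gain * d_own^0.15) + noise`,
floored at zero.  The concave ownership→arousal exponent is a modeling
choice of this package: defensive arousal saturates, so a weak but
affirmative illusion still triggers the automatic threat response.  A
linear link would make the vestibular contribution numerically
invisible given the default model profile.  Generator constants
(baseline median 0.30 mmho, attenuation 0.04 per repetition, gain 0.35,
noise SD median 0.10 mmho) were calibrated once so the realized
normalized congruence effects (~0.12 visuo-tactile, ~0.04
visuo-vestibular), the ~2% null-response rate (16/800), and the planned
contrast magnitudes sit at the scale such studies report, then frozen.
Condition orders follow the four printed pseudorandomization sequences,
counterbalanced; threat identities are a per-participant permutation of
1..16 (metadata only — they do not affect magnitudes).

What the generator does *not* emulate: raw electrodermal waveforms
(only per-trial magnitudes), order effects on the questionnaire,
drop-out, and any direct condition→SCR pathway that bypasses ownership.
Passing tests therefore show that the pipeline recovers structure *of
this generative family*, not that the model is the true account of any
particular dataset.

## The analysis pipeline

**Ordinal models.** Each statement is fitted with a cumulative link
mixed model: logit link (probit behind a flag), treatment coding with
asynchronous as reference, participant random intercept.  The marginal
likelihood integrates the random effect per participant by adaptive
Gauss–Hermite quadrature (10 nodes; nodes recentred at the conditional
mode found by Newton's method and rescaled by the local curvature;
log-sum-exp throughout).  No Python package fits this model class, so
the fitter is implemented here and checked against brute-force
numerical integration on toy data (1e-6 relative) and against the
plain cumulative-logit model when the random SD is zero.  Parameters
are transformed (first cutpoint + log-increments, log random SD) so the
constraints hold by construction; optimization is L-BFGS-B, with betas
bounded at ±15 and a separation warning if a bound is hit.  Fixed
effects are tested by likelihood-ratio tests against the nested model.
The 0–10 VAS statement is discretized to integer points so the same
ordinal machinery applies.

**Planned comparisons.** A Shapiro–Wilk gate (α = 0.05) on the paired
differences chooses between the Wilcoxon signed-rank test (zeros
dropped, mid-ranks; exact p by dynamic-programming enumeration of the
rank-sum distribution when n ≤ 25 without ties, otherwise normal
approximation with tie and continuity corrections) with matched-pairs
rank-biserial `r_C = 2V/T − 1`, and the paired t test with
`d_z = mean(d)/sd(d)`.  JZS Bayes factors (Cauchy prior scale √2/2 on
the standardized effect) are computed from the t statistic and n via
the inverse-gamma scale-mixture integral; an independent quadrature
over the effect size with the noncentral-t density serves as the test
oracle.  Post hoc power for the point-biserial model uses the
noncentral-t formulation.

**SCR.** Null responses are raw values below 0.01 mmho; magnitude
averages all trials, amplitude only elicited ones.  Responses are
range-normalized by each participant's maximum.  The mixed model
(repetition + VT + VV + VT×VV, random intercept, ML) is statsmodels
MixedLM; the robust variant wraps it in Huber-weighted IRLS (c = 1.345
on MAD-scaled residuals including the random-effect BLUP), with weights
entering by scaling the response, design, and random-intercept columns
by √w.  This approximates the published robust-LMM estimators; the
contamination property test bounds the divergence rather than claiming
equivalence.  When the variance component sits on the boundary the
default optimizer can fail to converge; the fit falls back to Powell.
The six planned contrasts follow the study's tails (five one-sided,
one two-sided).  "Null responders" are not operationally defined in
the literature this mirrors; the exclusion rule here is a configurable
median-raw threshold (default 0.02 mmho).

**Calibration and recovery.** The suite verifies: LRT type-I error
0.05 ± 0.03 under a null generator (200 simulations, 40 participants —
this size keeps the full+reduced refits fast while leaving binomial
noise at ±0.015); CLMM fixed effects recovered within 15% at 200
participants over 10 seeds (ML has a small positive bias, ~0.05 on the
logit scale, so recovery truths are of appreciable size); SCR effect
signs in ≥95/100 seeds at the 50×16 design size.

## Numerical choices and edge cases

- Log-odds are capped at ±30 inside the model and ±8 in the response
  link, keeping arithmetic finite when posteriors saturate.
- `d_own` is clipped into `[min(d_VT, d_VV), max(d_VT, d_VV)]` after
  the fixed point, removing the residual damping error (< 2e-6).
- Category probabilities are computed as `log F(a) + log1mexp` so tail
  categories do not underflow; derivative ratios are clipped where the
  probability is numerically zero (only the search direction matters
  there).
- Zero-variance populations (infinite prior concentration, zero sdlogs)
  are supported; correlation stages then report "undefined" rather
  than correlating numerical noise.
- Degenerate Wilcoxon input (all zero differences) and constant ordinal
  responses raise informative errors.

## Known limitations

- The model treats events as discrete onset pairs; no continuous-time
  dynamics of the oscillating rotation.
- The event-count reliability law fixes the VT:VV weight ratio for a
  given noise profile; only between-participant noise variation moves
  it.
- The robust LMM is an IRLS approximation, not the exact published
  robust estimator.
- One-sided Bayes factors are not implemented (two-sided BF_10 only).
- The correlation between the two synchronous-vestibular conditions is
  carried by participant-level response propensity; on the raw
  posterior probabilities alone the model implies a slightly negative
  association, so that check is defined on model-implied rating
  latents, not on `d_own` itself.
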