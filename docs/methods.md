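# Methods

This note documents the generative model behind the synthetic trial tables,
the fitting machinery, the numerical conventions, and the limits of what the
synthetic data can show.

## Coordinates and trial records

All directions are double-polar: azimuth α is the angle from the midsagittal
plane (positive rightward — the plugged side), elevation ε the angle from
the horizontal plane (positive upward), both in degrees at every interface.
Physical speaker targets satisfy |α| + |ε| ≤ 90°; the boundary check rounds
to 1e-9 before comparing so values sitting exactly on the 90° rim are not
rejected by float jitter. **Responses are deliberately exempt** from the
diamond invariant: a head-pointing response is unconstrained, and simulated
response noise may carry it outside the physically reachable target set.
Missing reaction times are an empty CSV field and `None` in memory, never 0.

## The generative listener

Each spatial channel is a one-dimensional Gaussian cue-combination problem:
a sensory likelihood N(μ_STIM, σ_STIM) meets a spatial prior
N(μ_PRIOR, σ_PRIOR). Writing g = σ²_P / (σ²_P + σ²_S):

| quantity | MAP rule | posterior sampling |
|---|---|---|
| response mean | g·μ_S + (1−g)·μ_P | same |
| response variance | g²·σ²_S | g·σ²_S |

The two variances differ by exactly 1 + σ²_S/σ²_P. They answer slightly
different questions: the MAP variance is the across-trial variability of the
posterior mean when the likelihood centre is itself a noisy sample of the
true direction, while the sampling variance is that of a random draw from
the posterior at the true centre. `simulate_trial` draws the response
directly from the closed-form response distribution (plus motor noise), so
the generator's across-trial moments match these formulas exactly under
both rules; the test suite verifies each against its own mechanistic
Monte-Carlo simulation. An infinite prior SD is the uniform-prior
(maximum-likelihood) limit: the response follows the likelihood.

### Condition-specific parameters

Defaults (every one overridable per model or via YAML):

| parameter | binaural | plugged, untrained | plugged, trained |
|---|---|---|---|
| azimuth prior (mean, SD) | (0°, 180°) ≈ uniform | (−40°, 15°) | (−18°, 43°) |
| elevation prior (mean, SD) | (+3°, 12°) | (+3°, 12°) | (+1°, 7.5°) |
| azimuth sensory SD | 3° | 30° | 15° |
| elevation sensory SD (hearing / plugged side) | 5° / – | 5° / 30° | 5° / 30° |

Rationale: binaural azimuth cues (interaural time and level differences)
are highly reliable, so azimuth behaves as maximum-likelihood estimation
(gain ≈ 1); the elevation prior width of 12° sits in the 10–15° range
typical of normal-hearing listeners and, against a 5° spectral-cue
likelihood, yields the familiar elevation gain of ~0.85 with a small upward
bias. Plugging removes the binaural cues: the azimuth likelihood widens to
30° and a narrow prior takes over at the azimuth implied by the perceived
interaural level difference, producing the characteristic low gain
(g ≈ 0.2) and large bias toward the hearing ear.

**Perceived-ILD azimuth prior.** Under plugged hearing the azimuth prior is
centred at `perceived_ild_bias_deg` (default −40°) plus a linear level
term, −0.5°/dB above the 60-dBA reference: louder sounds produce a larger
perceived ILD and push the percept further toward the hearing ear. This is
what makes the proximal-level weight p of the azimuth cue regression come
out negative on plugged sessions. The level dependence of the perceived ILD
is not an empirically measured function; the slope is a free modelling
parameter with a sign chosen to match the observed louder-is-more-biased
phenomenology. Low-passed stimuli are attenuated less by a plug
(20 vs 25 dB), so their prior shift is scaled by 20/25.

**Azimuth-dependent elevation reliability.** Elevation depends on spectral
pinna cues, and which ear's cues dominate depends on perceived azimuth.
Under plugging the elevation sensory SD interpolates logistically in target
azimuth between the hearing-side value (far left) and the plugged-side
value (far right), with slope 0.05 per degree (midpoint 0°). The resulting
elevation gain profile falls from near-binaural values on the hearing side
to near zero on the plugged side, passing through roughly a third of the
binaural gain at the midline. The logistic form is a modelling choice; only
its monotonicity matters for the analyses.

**Head shadow.** The proximal level at the free ear is
I_prox = I_snd + HSE·sin(α) dB with HSE = 10 dB — a sinusoidal
approximation valid in the frontal hemifield only (|α| ≤ 90°; the function
refuses values outside it).

**Motor noise and reaction time.** Independent Gaussian motor noise
(SD 3°) is added to both response components. Reaction time is plumbing for
the dynamics analyses, not a behavioral claim:
rt = (150 ms + 10 ms/° × mean posterior-response SD) × lognormal(0, 0.1).
Because the azimuth response SD grows as the prior relaxes, this simulated
RT does not reproduce the falling RT curves of trained human listeners.

### Training schedule

Feedback training is modelled as exponential relaxation: at trial t each
prior parameter is end + (start − end)·exp(−(t−1)/τ). The azimuth prior
widens (15° → 60°) and re-centres (−40° → −5°), the elevation prior
sharpens at the horizon (12° → 5°, where all feedback targets lie), and
the azimuth sensory SD falls (30° → 6°). The sensory-reliability term is
deliberate: priors-only relaxation would make response *scatter grow* as
g·σ_S rises, whereas trained listeners become more precise as well as more
accurate — the improvement partly reflects remapped sensory cues, not just
a released prior. The time constant defaults to τ = 500 trials, comparable
to the session length, so that improvement remains gradual across the whole
500-trial block rather than saturating early; this matches the steadily
rising windowed gain/r² curves of trained listeners. The post-test listener
is the trained state at trial 500 (not the schedule's asymptote).

### Randomness

A session is reproducible from one integer seed. The target/level menu uses
a session stream; each trial's response noise uses its own stream derived
from (seed, trial index), so changing the trial order can never silently
reshuffle noise across trials.

## Session designs

* `training` — ten azimuths (±12°, ±24°, ±36°, ±48°, ±60°, elevation 0)
  each presented n/10 times at HP 60 dBA in pseudo-random order (default
  n = 500).
* `pre_test` / `post_test` — default 180 trials of HP at 50/60/70 dBA in
  equal numbers; targets uniform over azimuth [−60°, +60°] and elevation
  [−40°, +50°] within the diamond, excluding the training locations.
* `control_binaural` / `control_plugged` — default 300 trials: HP at
  45–70 dBA in 5-dB steps plus LP and BB at 50/65 dBA, equal counts;
  azimuths span [−80°, +80°].

Trial counts can be scaled (in multiples of the menu size) when analyses
need more statistical power than the stock session sizes provide.

## Fitting conventions

* Simple fits use ordinary least squares (scipy); gain/bias are the OLS
  slope/intercept. **MAE** is the mean of |response − target| (raw
  localization error); the **residual SD** is the SD (ddof = 1) of the
  residuals around the fitted line. The two are kept distinct on purpose.
* z-scoring uses the sample SD (ddof = 1); a constant predictor raises
  "zero variance predictor" rather than propagating NaNs.
* The standardized cue regressions are fit **without intercept**
  (z-scoring centres every variable; the cue model has no constant term),
  via statsmodels OLS. The reported r² is that of the multiple regression
  on standardized variables.
* A session with a single sound level is refused outright: I_prox is then a
  deterministic monotone function of target azimuth and p/q are
  unidentifiable. A standardized design with condition number above 1e3
  fits but attaches a collinearity warning to the result.
* Hemifield splits select target azimuth < 0 (left) or > 0 (right);
  midline targets belong to neither.
* Windows are fully contained (no partial edge windows); window centers are
  mean trial indices. Azimuth bins use the *target* azimuth, inclusive left
  edge / exclusive right edge, and bins with fewer than 5 trials are
  reported missing (NaN) rather than fit on a handful of points.
* Cross-session aggregation of window/bin series is a mean ± SD per center;
  sessions missing a bin are excluded from that bin's statistics.

## Pipeline conventions

"Improvement" per regression parameter follows the diagonal convention of
pre/post scatter plots: gain and r² improve upward, |bias| and MAE improve
downward. The pooled improvements over levels × parameters feed an exact
one-sided sign test, P(X ≥ k), X ~ Binomial(n, ½); pooling treats the
parameters as independent, which they are not — the pooled p-value is a
descriptive summary, not a calibrated test. All artifacts (CSV/JSON) are
written with fixed numeric formatting so a fixed config reproduces them
byte-for-byte; the report embeds the config hash, stage seeds, and package
version.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* expected of this
paradigm: negative level weights and sub-unit azimuth weights under acute
plugging, hemifield-asymmetric elevation gains, gradual training curves,
and the pre→post improvement pattern in azimuth alongside degraded
elevation weights. Passing tests therefore demonstrate that the analysis
chain measures what it claims to measure on data of known ground truth.
They do **not** validate the listener model against human data: real
listeners differ idiosyncratically (some barely use spectral cues), real
cue remapping is not Gaussian-conjugate, reaction-time dynamics are not
modelled, and no claim is made that the default parameter values fit any
individual subject. Fitting this generative model to human sessions is out
of scope.

## Known limitations

* One synthetic listener per run; no between-subject variability model.
* The azimuth and elevation channels are conditionally independent given
  the target; real percepts interact (perceived azimuth, not target
  azimuth, weights the ears' spectral cues).
* The perceived-ILD level slope and the logistic reliability profile are
  structural assumptions, identifiable only in sign from the analyses here.
* Posterior sampling is available as a decision rule but the stock
  configurations use MAP; response-variance-based model comparison between
  the two rules is left to the user.
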