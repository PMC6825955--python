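# monaural-adapt

Simulation and analysis tools for **acute monaural sound-localization
adaptation** experiments: what happens to a listener's azimuth and elevation
percepts when one ear is plugged, and how a short session of visual-feedback
training re-weights the available acoustic cues.

The package is aimed at auditory psychophysicists who work with
stimulus–response localization data in double-polar coordinates (azimuth α,
elevation ε, with |α| + |ε| ≤ 90° in the frontal hemifield). It provides:

* **A generative Bayesian listener** (`monaural_adapt.listener`). Each
  spatial channel combines a Gaussian sensory likelihood N(μ_STIM, σ_STIM)
  with a Gaussian spatial prior N(μ_PRIOR, σ_PRIOR). With
  g = σ²_PRIOR / (σ²_PRIOR + σ²_STIM), the response distribution is

  - mean: μ_RESP = g·μ_STIM + (1 − g)·μ_PRIOR (both decision rules),
  - variance: σ²_RESP = g²·σ²_STIM under the optimal **MAP** rule, and
    σ²_RESP = g·σ²_STIM under **posterior sampling** — exactly
    (1 + σ²_STIM/σ²_PRIOR) times larger.

  Plugging is modelled as (i) a noisy azimuth likelihood dominated by a
  narrow prior centred on the perceived interaural-level-difference
  direction (level-dependent, biased toward the hearing ear), and (ii) an
  elevation likelihood whose reliability interpolates logistically with
  azimuth between the hearing and plugged sides. Feedback training relaxes
  the azimuth prior, sharpens the elevation prior at the horizon, and
  improves azimuth sensory reliability, trial by trial.

* **The regression suite** (`monaural_adapt.regression`). Simple
  stimulus–response fits R = a + b·T with gain, bias, r, r², residual SD and
  mean absolute error; and standardized cue-weight regressions on z-scored
  variables,

      ẑ(Rα) = p·ẑ(I_prox) + q·ẑ(Tα)
      ẑ(Rε) = p·ẑ(I_prox) + q·ẑ(Tα) + s·ẑ(Tε)

  where I_prox = I_snd + HSE·sin(Tα) is the head-shadow-modulated proximal
  sound level (HSE = 10 dB by default). An ideal localizer gives
  (p, q) = (0, 1) and (p, q, s) = (0, 0, 1).

* **Dynamics analyses** (`monaural_adapt.dynamics`): a 50-trial / 5-step
  sliding-window regression through the training block, and local elevation
  gain in 20°-wide azimuth bins stepped 5° from −80° to +60°.

* **An end-to-end pipeline + CLI** (`monaural_adapt.pipeline`,
  `monaural-adapt`): simulate pre-test → training → post-test, fit
  everything, and produce a pre/post comparison report with an exact
  one-sided sign test over the regression-parameter improvements.

## Worked example

```bash
monaural-adapt run --out experiment/ --seed 1
cat experiment/summary.txt
```

prints

```
monaural-adapt experiment summary
seed: 1   config: a4bbadc1c789
trials: pre 180, training 500, post 180
azimuth cue weights pre:  p=-0.530 q=+0.914
azimuth cue weights post: p=+0.025 q=+0.901
sign test: 12/12 parameters improved, one-sided p = 0.000244
```

Reading the numbers: before training the plugged listener's azimuth
responses carry a clearly negative proximal-level weight (p = −0.53 — louder
sounds are heard further toward the unplugged ear, the head-shadow
signature) while the azimuth weight q is below its ideal value of 1. After
training the level weight has collapsed toward zero and all twelve
per-level regression parameters (gain, |bias|, r², MAE at 50, 60 and
70 dBA) have moved in the improvement direction, which an exact binomial
sign test puts at p ≈ 2.4 × 10⁻⁴. The full per-level fits are in
`experiment/fits.json` (e.g. azimuth gain 0.16 → 0.91 and MAE 37° → 12° on
this seed), the sliding-window training series and binned elevation gains
in `experiment/dynamics.csv`.

The same steps are available individually (`monaural-adapt simulate / fit /
dynamics / report`); see `configs/default_experiment.yaml` for the
commented configuration schema, and `docs/methods.md` for the model and its
assumptions.

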