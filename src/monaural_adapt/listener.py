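"""Generative Bayesian listener for monaural-plugging localization experiments.

The simulator produces synthetic stimulus–response trial tables with the
statistical structure expected of normal-hearing, acutely ear-plugged, and
feedback-trained listeners:

* **Azimuth channel.**  The sensory likelihood is centred on the true target
  azimuth with a condition-dependent reliability.  Under binaural hearing the
  spatial prior is nearly uniform, so the percept follows the stimulus
  (gain ≈ 1).  Under acute plugging the listener adopts a narrow azimuth
  prior centred on the direction implied by the perceived interaural level
  difference — biased toward the hearing ear, and further so for louder
  sounds — which produces the characteristic low gain and large ear-ward
  bias.  Feedback training relaxes (widens and re-centres) this prior.

* **Elevation channel.**  Spectral (pinna) cues drive elevation.  Their
  reliability depends on which ear hears the sound: under plugging, the
  sensory SD interpolates logistically with target azimuth between a good
  (hearing-side) and a poor (plugged-side) value, so the elevation gain
  falls off from the hearing to the plugged hemifield.  Training at
  zero-elevation targets sharpens the elevation prior around the horizon,
  lowering elevation gain everywhere.

* **Decision rules.**  Prior and likelihood are combined into a Gaussian
  posterior.  The optimal maximum-a-posteriori (MAP) rule responds at the
  posterior mean; the posterior-sampling rule draws the response from the
  posterior, inflating response variance by a factor ``1 + σS²/σP²``.

* **Proximal level.**  The head-shadow effect (HSE) is modelled as a
  sinusoidal dB modulation of the free-field level with magnitude
  ``hse_db`` (default 10 dB).

All angles are degrees, all levels dBA, all times milliseconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .trials import (
    TRAINING_AZIMUTHS_DEG,
    Condition,
    DoublePolarDirection,
    Phase,
    StimulusType,
    TrialRecord,
)

__all__ = [
    "GaussianPrior",
    "Likelihood",
    "ResponseDistribution",
    "DecisionRule",
    "ListenerCondition",
    "ListenerModel",
    "TrainingSchedule",
    "proximal_level",
    "posterior_response",
    "simulate_trial",
    "simulate_session",
    "SESSION_DESIGNS",
    "default_training_schedule",
]


class DecisionRule(enum.Enum):
    MAP = "map"
    POSTERIOR_SAMPLE = "posterior_sample"


class ListenerCondition(enum.Enum):
    BINAURAL = "binaural"
    PLUGGED_PRE = "plugged_pre"
    PLUGGED_TRAINING = "plugged_training"
    PLUGGED_POST = "plugged_post"


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian spatial prior; ``sd_deg = inf`` gives the uniform limit."""

    mean_deg: float
    sd_deg: float

    def __post_init__(self) -> None:
        if not self.sd_deg > 0:
            raise ValueError(f"prior sd must be > 0, got {self.sd_deg}")


@dataclass(frozen=True)
class Likelihood:
    """Gaussian sensory likelihood; sd is the uncertainty of the encoding."""

    mean_deg: float
    sd_deg: float

    def __post_init__(self) -> None:
        if not (self.sd_deg > 0 and math.isfinite(self.sd_deg)):
            raise ValueError(f"likelihood sd must be finite and > 0, got {self.sd_deg}")


@dataclass(frozen=True)
class ResponseDistribution:
    """Across-trial response distribution implied by prior, likelihood, rule."""

    mean_deg: float
    sd_deg: float


def proximal_level(
    target_azimuth_deg: float, free_field_level_dBA: float, hse_db: float = 10.0
) -> float:
    """Perceived level at the free ear: free-field level plus the sinusoidal
    head-shadow modulation, ``I + HSE * sin(azimuth)`` in dB.

    Valid only in the frontal hemifield (|azimuth| <= 90 deg), where the sine
    approximates the azimuth dependence of the head shadow.
    """
    if abs(target_azimuth_deg) > 90.0:
        raise ValueError(
            f"azimuth {target_azimuth_deg:g} outside the frontal hemifield (±90°)"
        )
    return free_field_level_dBA + hse_db * math.sin(math.radians(target_azimuth_deg))


def posterior_response(
    prior: GaussianPrior,
    likelihood: Likelihood,
    rule: DecisionRule = DecisionRule.MAP,
) -> ResponseDistribution:
    """Across-trial response distribution for a Gaussian prior × likelihood.

    With shrinkage factor ``g = σP² / (σP² + σS²)`` the response mean is the
    posterior mean ``g·μS + (1−g)·μP`` for both rules.  The response variance
    is ``g²·σS²`` under the MAP rule (the posterior mean of a noisy sensory
    sample) and ``g·σS²`` under posterior sampling (a random draw from the
    posterior), larger by exactly ``1 + σS²/σP²``.  An infinite prior SD
    gives the uniform-prior limit: mean ``μS``, variance ``σS²``.
    """
    rule = DecisionRule(rule)
    sp, ss = prior.sd_deg, likelihood.sd_deg
    if math.isinf(sp):
        g = 1.0
    else:
        g = sp**2 / (sp**2 + ss**2)
    mean = g * likelihood.mean_deg + (1.0 - g) * prior.mean_deg
    if rule is DecisionRule.MAP:
        sd = g * ss
    else:
        sd = math.sqrt(g) * ss
    return ResponseDistribution(mean_deg=mean, sd_deg=sd)


@dataclass(frozen=True)
class ListenerModel:
    """Generative parameters for one hearing condition.

    The stock configurations (:meth:`binaural`, :meth:`plugged_pre`,
    :meth:`plugged_post`, :meth:`ideal`) encode the modelling defaults; every
    field can be overridden.  Under plugged conditions the azimuth prior is
    centred on the perceived-ILD direction ``perceived_ild_bias_deg`` (scaled
    by the stimulus-specific plug attenuation and shifted by
    ``ild_bias_level_slope_deg_per_db`` per dB above the 60-dBA reference);
    under binaural hearing ``azimuth_prior`` is used as given.
    """

    condition: ListenerCondition
    azimuth_prior: GaussianPrior
    elevation_prior: GaussianPrior
    azimuth_sensory_sd_deg: float
    elevation_sensory_sd_hearing_deg: float
    elevation_sensory_sd_plugged_deg: float
    binaural_weight_slope: float = 0.05  # logistic slope, per degree azimuth
    hse_db: float = 10.0
    plug_attenuation_hp_db: float = 25.0
    plug_attenuation_lp_db: float = 20.0
    perceived_ild_bias_deg: float = 0.0
    ild_bias_level_slope_deg_per_db: float = 0.0
    reference_level_dBA: float = 60.0
    decision_rule: DecisionRule = DecisionRule.MAP
    motor_noise_sd_deg: float = 3.0
    azimuth_sensory_sd_by_stimulus: Optional[Mapping[StimulusType, float]] = None
    rt_base_ms: float = 150.0
    rt_ms_per_deg: float = 10.0
    rt_lognormal_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "azimuth_sensory_sd_deg",
            "elevation_sensory_sd_hearing_deg",
            "elevation_sensory_sd_plugged_deg",
            "plug_attenuation_hp_db",
            "plug_attenuation_lp_db",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.motor_noise_sd_deg < 0:
            raise ValueError("motor_noise_sd_deg must be >= 0")

    # -- stock configurations -------------------------------------------------

    @classmethod
    def binaural(cls, **overrides) -> "ListenerModel":
        """Normal-hearing listener: near-uniform azimuth prior, mildly
        informative elevation prior a few degrees above the horizon."""
        kw = dict(
            condition=ListenerCondition.BINAURAL,
            azimuth_prior=GaussianPrior(0.0, 180.0),
            elevation_prior=GaussianPrior(3.0, 12.0),
            azimuth_sensory_sd_deg=3.0,
            elevation_sensory_sd_hearing_deg=5.0,
            elevation_sensory_sd_plugged_deg=30.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def plugged_pre(cls, **overrides) -> "ListenerModel":
        """Acutely plugged, untrained: noisy azimuth cues dominated by a
        narrow prior at the perceived-ILD direction (hearing-ear side)."""
        kw = dict(
            condition=ListenerCondition.PLUGGED_PRE,
            azimuth_prior=GaussianPrior(-40.0, 15.0),
            elevation_prior=GaussianPrior(3.0, 12.0),
            azimuth_sensory_sd_deg=30.0,
            elevation_sensory_sd_hearing_deg=5.0,
            elevation_sensory_sd_plugged_deg=30.0,
            perceived_ild_bias_deg=-40.0,
            ild_bias_level_slope_deg_per_db=-0.5,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def plugged_post(cls, **overrides) -> "ListenerModel":
        """Plugged after feedback training: relaxed, re-centred azimuth prior,
        improved (remapped) azimuth reliability, and a sharpened elevation
        prior at the trained horizon.  Values match the trained state reached
        after 500 trials of the default :class:`TrainingSchedule`."""
        kw = dict(
            condition=ListenerCondition.PLUGGED_POST,
            azimuth_prior=GaussianPrior(-18.0, 43.0),
            elevation_prior=GaussianPrior(1.0, 7.5),
            azimuth_sensory_sd_deg=15.0,
            elevation_sensory_sd_hearing_deg=5.0,
            elevation_sensory_sd_plugged_deg=30.0,
            perceived_ild_bias_deg=-18.0,
            ild_bias_level_slope_deg_per_db=-0.5,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def ideal(cls, **overrides) -> "ListenerModel":
        """Noiseless veridical localizer: uniform priors, negligible sensory
        and motor noise.  Responses equal targets to numerical precision."""
        kw = dict(
            condition=ListenerCondition.BINAURAL,
            azimuth_prior=GaussianPrior(0.0, math.inf),
            elevation_prior=GaussianPrior(0.0, math.inf),
            azimuth_sensory_sd_deg=1e-9,
            elevation_sensory_sd_hearing_deg=1e-9,
            elevation_sensory_sd_plugged_deg=1e-9,
            motor_noise_sd_deg=0.0,
        )
        kw.update(overrides)
        return cls(**kw)

    # -- derived per-trial quantities ----------------------------------------

    @property
    def is_plugged(self) -> bool:
        return self.condition is not ListenerCondition.BINAURAL

    def _ild_attenuation_scale(self, stimulus_type: StimulusType) -> float:
        # LP sounds are attenuated less by the plug, so the perceived ILD
        # (and the prior shift it induces) is proportionally smaller.
        if stimulus_type is StimulusType.LP:
            return self.plug_attenuation_lp_db / self.plug_attenuation_hp_db
        return 1.0

    def effective_azimuth_prior(
        self, stimulus_type: StimulusType, level_dBA: float
    ) -> GaussianPrior:
        if not self.is_plugged:
            return self.azimuth_prior
        mean = (
            self.perceived_ild_bias_deg * self._ild_attenuation_scale(stimulus_type)
            + self.ild_bias_level_slope_deg_per_db
            * (level_dBA - self.reference_level_dBA)
        )
        return GaussianPrior(mean, self.azimuth_prior.sd_deg)

    def azimuth_sensory_sd(self, stimulus_type: StimulusType) -> float:
        if self.azimuth_sensory_sd_by_stimulus is not None:
            return self.azimuth_sensory_sd_by_stimulus.get(
                stimulus_type, self.azimuth_sensory_sd_deg
            )
        return self.azimuth_sensory_sd_deg

    def elevation_sensory_sd(self, target_azimuth_deg: float) -> float:
        """Spectral-cue reliability; under plugging the perceived azimuth acts
        as a binaural weighting factor, degrading the plugged side."""
        if not self.is_plugged:
            return self.elevation_sensory_sd_hearing_deg
        w = 1.0 / (1.0 + math.exp(-self.binaural_weight_slope * target_azimuth_deg))
        return self.elevation_sensory_sd_hearing_deg + w * (
            self.elevation_sensory_sd_plugged_deg
            - self.elevation_sensory_sd_hearing_deg
        )


def simulate_trial(
    model: ListenerModel,
    target: DoublePolarDirection,
    stimulus_type: StimulusType,
    level_dBA: float,
    rng: np.random.Generator,
    *,
    trial_index: int = 1,
    phase: Phase = Phase.PRE,
) -> TrialRecord:
    """Simulate one trial: Bayesian combination per channel, decision rule,
    motor noise, and a reaction time decreasing with posterior precision."""
    if not target.within_frontal_hemifield():
        raise ValueError(
            f"target ({target.azimuth_deg:g}, {target.elevation_deg:g}) outside "
            "the double-polar diamond"
        )
    stimulus_type = StimulusType(stimulus_type)

    az_prior = model.effective_azimuth_prior(stimulus_type, level_dBA)
    az_lik = Likelihood(target.azimuth_deg, model.azimuth_sensory_sd(stimulus_type))
    rd_az = posterior_response(az_prior, az_lik, model.decision_rule)

    el_lik = Likelihood(
        target.elevation_deg, model.elevation_sensory_sd(target.azimuth_deg)
    )
    rd_el = posterior_response(model.elevation_prior, el_lik, model.decision_rule)

    resp_az = rng.normal(rd_az.mean_deg, rd_az.sd_deg) + rng.normal(
        0.0, model.motor_noise_sd_deg
    )
    resp_el = rng.normal(rd_el.mean_deg, rd_el.sd_deg) + rng.normal(
        0.0, model.motor_noise_sd_deg
    )

    mean_post_sd = 0.5 * (rd_az.sd_deg + rd_el.sd_deg)
    rt = (model.rt_base_ms + model.rt_ms_per_deg * mean_post_sd) * math.exp(
        rng.normal(0.0, model.rt_lognormal_sd)
    )

    return TrialRecord(
        trial_index=trial_index,
        phase=phase,
        condition=Condition.PLUGGED if model.is_plugged else Condition.BINAURAL,
        stimulus_type=stimulus_type,
        level_dBA=level_dBA,
        target=target,
        response=DoublePolarDirection(resp_az, resp_el),
        reaction_time_ms=rt,
    )


@dataclass(frozen=True)
class TrainingSchedule:
    """Exponential relaxation of the spatial priors over the training block.

    At trial ``t`` (1-based) each parameter is
    ``end + (start − end) · exp(−(t−1)/τ)`` with ``τ = time_constant_trials``.
    The azimuth prior widens and re-centres toward the midline; the elevation
    prior sharpens around the horizon (where all feedback targets lie); and
    the azimuth sensory reliability improves (cue remapping), without which
    the response scatter would grow as the prior releases its grip —
    feedback training makes responses both more accurate and more precise.
    """

    n_trials: int = 500
    azimuth_prior_start: GaussianPrior = field(
        default_factory=lambda: GaussianPrior(-40.0, 15.0)
    )
    azimuth_prior_end: GaussianPrior = field(
        default_factory=lambda: GaussianPrior(-5.0, 60.0)
    )
    elevation_prior_start: GaussianPrior = field(
        default_factory=lambda: GaussianPrior(3.0, 12.0)
    )
    elevation_prior_end: GaussianPrior = field(
        default_factory=lambda: GaussianPrior(0.0, 5.0)
    )
    azimuth_sensory_sd_start_deg: float = 30.0
    azimuth_sensory_sd_end_deg: float = 6.0
    time_constant_trials: float = 500.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.time_constant_trials > 0:
            raise ValueError("time_constant_trials must be > 0")

    def prior_at(self, trial: int) -> tuple[GaussianPrior, GaussianPrior]:
        """Interpolated (azimuth, elevation) priors at 1-based trial number."""
        f = math.exp(-(trial - 1) / self.time_constant_trials)

        def interp(a: GaussianPrior, b: GaussianPrior) -> GaussianPrior:
            return GaussianPrior(
                b.mean_deg + (a.mean_deg - b.mean_deg) * f,
                b.sd_deg + (a.sd_deg - b.sd_deg) * f,
            )

        return (
            interp(self.azimuth_prior_start, self.azimuth_prior_end),
            interp(self.elevation_prior_start, self.elevation_prior_end),
        )

    def azimuth_sensory_sd_at(self, trial: int) -> float:
        f = math.exp(-(trial - 1) / self.time_constant_trials)
        return self.azimuth_sensory_sd_end_deg + (
            self.azimuth_sensory_sd_start_deg - self.azimuth_sensory_sd_end_deg
        ) * f


def default_training_schedule(**overrides) -> TrainingSchedule:
    return TrainingSchedule(**overrides)


#: design token -> (phase tag, expected plugged?)
SESSION_DESIGNS = {
    "control_binaural": (Phase.CONTROL, False),
    "control_plugged": (Phase.CONTROL, True),
    "pre_test": (Phase.PRE, True),
    "training": (Phase.TRAINING, True),
    "post_test": (Phase.POST, True),
}

_TEST_LEVELS_DBA = (50.0, 60.0, 70.0)
_CONTROL_MENU = tuple(
    [(StimulusType.HP, lvl) for lvl in (45.0, 50.0, 55.0, 60.0, 65.0, 70.0)]
    + [(StimulusType.LP, lvl) for lvl in (50.0, 65.0)]
    + [(StimulusType.BB, lvl) for lvl in (50.0, 65.0)]
)


def _draw_target(
    rng: np.random.Generator, az_range: tuple[float, float],
    el_range: tuple[float, float],
) -> DoublePolarDirection:
    # azimuth uniform, elevation uniform within the diamond-clipped range
    while True:
        az = rng.uniform(*az_range)
        lo = max(el_range[0], -(90.0 - abs(az)))
        hi = min(el_range[1], 90.0 - abs(az))
        el = rng.uniform(lo, hi)
        tgt = DoublePolarDirection(az, el)
        if tgt.within_frontal_hemifield():
            return tgt


def simulate_session(
    model: ListenerModel,
    design: str,
    seed: int,
    *,
    schedule: Optional[TrainingSchedule] = None,
    n_trials: Optional[int] = None,
) -> list[TrialRecord]:
    """Simulate a full experimental session.

    Designs
    -------
    ``control_binaural`` / ``control_plugged``
        300 trials (default): HP at 45–70 dBA in 5-dB steps plus LP and BB at
        50/65 dBA, 30 locations each, azimuths in [−80, +80] and elevations
        in [−40, +50] within the double-polar diamond.
    ``pre_test`` / ``post_test``
        180 trials (default) of HP50/HP60/HP70 in equal numbers, azimuths in
        [−60, +60], elevations in [−40, +50], excluding the ten training
        locations.
    ``training``
        The feedback block: each of the ten azimuths (±12…±60, elevation 0)
        presented equally often at HP 60 dBA in pseudo-random order; with a
        :class:`TrainingSchedule` the priors are interpolated trial-by-trial.

    The session is reproducible from ``seed``: the target/level menu uses one
    stream and each trial's response noise a per-trial stream derived from
    ``(seed, trial_index)``, so reordering never reshuffles noise.
    """
    if design not in SESSION_DESIGNS:
        raise ValueError(
            f"unknown design '{design}'; expected one of {sorted(SESSION_DESIGNS)}"
        )
    phase, plugged = SESSION_DESIGNS[design]
    if plugged != model.is_plugged:
        raise ValueError(
            f"design '{design}' requires a "
            f"{'plugged' if plugged else 'binaural'} listener model"
        )

    menu_rng = np.random.default_rng(np.random.SeedSequence([seed]))

    plan: list[tuple[DoublePolarDirection, StimulusType, float]] = []
    if design == "training":
        n = n_trials or (schedule.n_trials if schedule is not None else 500)
        if n % len(TRAINING_AZIMUTHS_DEG) != 0:
            raise ValueError(
                f"training trial count {n} must be a multiple of "
                f"{len(TRAINING_AZIMUTHS_DEG)}"
            )
        reps = n // len(TRAINING_AZIMUTHS_DEG)
        azimuths = np.repeat(TRAINING_AZIMUTHS_DEG, reps)
        menu_rng.shuffle(azimuths)
        plan = [
            (DoublePolarDirection(float(az), 0.0), StimulusType.HP, 60.0)
            for az in azimuths
        ]
    elif design in ("pre_test", "post_test"):
        n = n_trials or 180
        if n % len(_TEST_LEVELS_DBA) != 0:
            raise ValueError(f"test trial count {n} must be a multiple of 3")
        levels = np.repeat(_TEST_LEVELS_DBA, n // len(_TEST_LEVELS_DBA))
        menu_rng.shuffle(levels)
        for lvl in levels:
            while True:
                tgt = _draw_target(menu_rng, (-60.0, 60.0), (-40.0, 50.0))
                if not (
                    tgt.elevation_deg == 0.0
                    and tgt.azimuth_deg in TRAINING_AZIMUTHS_DEG
                ):
                    break
            plan.append((tgt, StimulusType.HP, float(lvl)))
    else:  # control designs
        n = n_trials or 300
        if n % len(_CONTROL_MENU) != 0:
            raise ValueError(
                f"control trial count {n} must be a multiple of {len(_CONTROL_MENU)}"
            )
        combos = np.repeat(np.arange(len(_CONTROL_MENU)), n // len(_CONTROL_MENU))
        menu_rng.shuffle(combos)
        for idx in combos:
            st, lvl = _CONTROL_MENU[int(idx)]
            plan.append((_draw_target(menu_rng, (-80.0, 80.0), (-40.0, 50.0)), st, lvl))

    trials: list[TrialRecord] = []
    for i, (tgt, st, lvl) in enumerate(plan, start=1):
        trial_model = model
        if design == "training" and schedule is not None:
            az_prior, el_prior = schedule.prior_at(i)
            trial_model = replace(
                model,
                azimuth_prior=az_prior,
                elevation_prior=el_prior,
                perceived_ild_bias_deg=az_prior.mean_deg,
                azimuth_sensory_sd_deg=schedule.azimuth_sensory_sd_at(i),
            )
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        trials.append(
            simulate_trial(
                trial_model, tgt, st, lvl, rng, trial_index=i, phase=phase
            )
        )
    return trials
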