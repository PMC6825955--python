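"""Stimulus–response fits and standardized cue-weighting regressions.

Two families of fits are provided:

1. Simple linear stimulus–response regressions, ``R = a + b·T``, separately
   for the azimuth and elevation components, with their summary statistics
   (gain ``b``, bias ``a``, Pearson ``r``, ``r²``, residual SD, and the mean
   absolute localization error ``mean |R − T|``).  An ideal localizer has
   gain 1 and bias 0.

2. Standardized multiple regressions of the z-scored response on z-scored
   cue predictors, fit without intercept (z-scoring centres everything):

   * azimuth:   ``ẑ(Rα) = p·ẑ(I_prox) + q·ẑ(Tα)``
   * elevation: ``ẑ(Rε) = p·ẑ(I_prox) + q·ẑ(Tα) + s·ẑ(Tε)``

   where ``I_prox = I_snd + HSE·sin(Tα)`` is the proximal (head-shadow
   modulated) sound level at the free ear.  The dimensionless coefficients
   p, q, s compare the relative contributions of perceived level, target
   azimuth, and target elevation.  An ideal localizer yields ``p=0, q=1``
   for azimuth and ``[p,q,s] = [0,0,1]`` for elevation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .listener import proximal_level
from .trials import TrialRecord

__all__ = [
    "FitResult",
    "CueWeights",
    "zscore",
    "fit_stimulus_response",
    "fit_azimuth_cues",
    "fit_elevation_cues",
    "CollinearityError",
    "CollinearityWarning",
]

#: Condition number above which a standardized design is flagged near-collinear.
CONDITION_NUMBER_LIMIT = 1e3


class CollinearityError(ValueError):
    """The standardized cue design is unidentifiable (e.g. one sound level)."""


class CollinearityWarning(UserWarning):
    """The standardized cue design is poorly conditioned."""


@dataclass(frozen=True)
class FitResult:
    """Summary of a 1-D linear stimulus–response fit."""

    gain: float
    bias_deg: float
    r: float
    r2: float
    residual_sd_deg: float
    mae_deg: float
    n: int

    def to_dict(self) -> dict:
        return {
            "gain": self.gain,
            "bias_deg": self.bias_deg,
            "r": self.r,
            "r2": self.r2,
            "residual_sd_deg": self.residual_sd_deg,
            "mae_deg": self.mae_deg,
            "n": self.n,
        }


@dataclass(frozen=True)
class CueWeights:
    """Standardized partial regression coefficients of the cue model.

    ``s`` is ``None`` for the two-predictor azimuth model.  A poorly
    conditioned design attaches a warning message instead of failing.
    """

    p: float
    q: float
    r2: float
    n: int
    s: Optional[float] = None
    condition_number: float = float("nan")
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"p": self.p, "q": self.q, "r2": self.r2, "n": self.n}
        if self.s is not None:
            d["s"] = self.s
        if self.warning:
            d["warning"] = self.warning
        return d


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 and *sample* SD 1 (ddof=1).

    Raises ``ValueError`` on fewer than two values or a zero-variance input
    (e.g. a single-level session fed to the azimuth cue model).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"zscore needs at least 2 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance predictor")
    return (x - x.mean()) / sd


def fit_stimulus_response(
    targets_deg: Sequence[float], responses_deg: Sequence[float]
) -> FitResult:
    """Ordinary least-squares fit ``response = bias + gain · target``.

    ``mae_deg`` is the mean absolute localization error, computed on the raw
    response − target differences (not the fit residuals); the residual SD
    is computed on the residuals around the fitted line (ddof=1).
    """
    t = np.asarray(targets_deg, dtype=float)
    r = np.asarray(responses_deg, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"length mismatch: {t.shape} targets vs {r.shape} responses")
    n = t.size
    if n < 3:
        raise ValueError(f"need at least 3 trials, got {n}")
    if t.std() == 0:
        raise ValueError("degenerate fit: target variance is zero")

    res = stats.linregress(t, r)
    resid = r - (res.intercept + res.slope * t)
    return FitResult(
        gain=float(res.slope),
        bias_deg=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        residual_sd_deg=float(np.std(resid, ddof=1)),
        mae_deg=float(np.mean(np.abs(r - t))),
        n=n,
    )


def _standardized_fit(
    response: np.ndarray, predictors: dict[str, np.ndarray], n_min: int
) -> tuple[dict[str, float], float, float, Optional[str]]:
    n = response.size
    if n < n_min:
        raise ValueError(f"need at least {n_min} trials, got {n}")
    zr = zscore(response)
    X = np.column_stack([zscore(v) for v in predictors.values()])
    cond = float(np.linalg.cond(X))
    warning = None
    if cond > CONDITION_NUMBER_LIMIT:
        warning = (
            f"near-collinear standardized design (condition number {cond:.3g})"
        )
        warnings.warn(warning, CollinearityWarning, stacklevel=3)
    model = sm.OLS(zr, X)  # no intercept: variables are centred by z-scoring
    fit = model.fit()
    coefs = dict(zip(predictors.keys(), (float(b) for b in fit.params)))
    ss_res = float(np.sum(fit.resid**2))
    ss_tot = float(np.sum(zr**2))
    r2 = 1.0 - ss_res / ss_tot
    return coefs, r2, cond, warning


def _prepare_cue_inputs(trials: Sequence[TrialRecord], hse_db: float):
    trials = list(trials)
    levels = np.array([t.level_dBA for t in trials])
    if np.unique(levels).size < 2:
        raise CollinearityError(
            "azimuth/elevation cue models need >= 2 distinct sound levels: with "
            "a single level the proximal level is a deterministic function of "
            "target azimuth and p/q are unidentifiable"
        )
    iprox = np.array(
        [proximal_level(t.target.azimuth_deg, t.level_dBA, hse_db) for t in trials]
    )
    t_az = np.array([t.target.azimuth_deg for t in trials])
    return trials, iprox, t_az


def fit_azimuth_cues(
    trials: Sequence[TrialRecord], hse_db: float = 10.0
) -> CueWeights:
    """Standardized two-predictor azimuth cue model: proximal level and
    target azimuth as predictors of the azimuth response."""
    trials, iprox, t_az = _prepare_cue_inputs(trials, hse_db)
    r_az = np.array([t.response.azimuth_deg for t in trials])
    coefs, r2, cond, warning = _standardized_fit(
        r_az, {"p": iprox, "q": t_az}, n_min=10
    )
    return CueWeights(
        p=coefs["p"], q=coefs["q"], r2=r2, n=len(trials),
        condition_number=cond, warning=warning,
    )


def fit_elevation_cues(
    trials: Sequence[TrialRecord],
    hse_db: float = 10.0,
    hemifield: str = "all",
) -> CueWeights:
    """Standardized three-predictor elevation cue model.

    ``hemifield`` restricts to targets with azimuth < 0 (``"left"``) or
    azimuth > 0 (``"right"``); midline targets (azimuth exactly 0) belong to
    neither hemifield.
    """
    if hemifield not in ("all", "left", "right"):
        raise ValueError(f"hemifield must be 'all', 'left' or 'right', got '{hemifield}'")
    trials = list(trials)
    if hemifield == "left":
        trials = [t for t in trials if t.target.azimuth_deg < 0]
    elif hemifield == "right":
        trials = [t for t in trials if t.target.azimuth_deg > 0]
    if len(trials) < 10:
        raise ValueError(
            f"fewer than 10 trials after '{hemifield}' hemifield filtering "
            f"({len(trials)})"
        )
    trials, iprox, t_az = _prepare_cue_inputs(trials, hse_db)
    t_el = np.array([t.target.elevation_deg for t in trials])
    r_el = np.array([t.response.elevation_deg for t in trials])
    coefs, r2, cond, warning = _standardized_fit(
        r_el, {"p": iprox, "q": t_az, "s": t_el}, n_min=10
    )
    return CueWeights(
        p=coefs["p"], q=coefs["q"], s=coefs["s"], r2=r2, n=len(trials),
        condition_number=cond, warning=warning,
    )
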