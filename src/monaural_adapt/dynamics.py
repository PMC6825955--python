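"""Windowed training-dynamics and azimuth-binned local-gain analyses.

Two sliding analyses quantify how localization behaviour changes:

* :func:`windowed_training_metrics` slides a fixed-size trial window (default
  50 trials, 5-trial steps) through a training session and fits the azimuth
  stimulus–response regression within each window, tracking gain, r², MAE,
  and mean reaction time as learning proceeds.

* :func:`local_elevation_gain` slides an azimuth bin (default 20° wide,
  5° steps, centres −80° … +60°) across the frontal hemifield and fits the
  elevation stimulus–response regression within each bin, exposing the
  azimuth dependence of the elevation gain (the binaural-weighting
  signature of monaural plugging).

Windows are fully contained (no partial edge windows); bins with fewer than
``min_count`` trials are reported as missing (NaN), never fit on a handful
of points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regression import fit_stimulus_response
from .trials import TrialRecord

__all__ = [
    "WindowSeries",
    "windowed_training_metrics",
    "local_elevation_gain",
    "aggregate_series",
]


@dataclass
class WindowSeries:
    """Per-window (or per-bin) statistics on a common grid of centers.

    ``centers`` are trial-window midpoints (trial index units) or azimuth
    bin centers (degrees).  Any metric may be absent (``None``); present
    metrics are parallel to ``centers`` with NaN marking under-filled
    windows/bins.
    """

    centers: np.ndarray
    window_size: float
    step: float
    min_count: int
    gain: Optional[np.ndarray] = None
    r2: Optional[np.ndarray] = None
    mae_deg: Optional[np.ndarray] = None
    rt_ms: Optional[np.ndarray] = None
    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for name in ("gain", "r2", "mae_deg", "rt_ms"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.centers):
                raise ValueError(f"metric '{name}' length != centers length")

    def to_frame(self) -> pd.DataFrame:
        data = {"center": self.centers}
        for name in ("gain", "r2", "mae_deg", "rt_ms"):
            arr = getattr(self, name)
            if arr is not None:
                data[name] = arr
        data["n"] = self.counts
        return pd.DataFrame(data)


def n_windows(n_trials: int, window: int, step: int) -> int:
    """Number of fully contained windows: ``(n − window)//step + 1``."""
    if n_trials < window:
        return 0
    return (n_trials - window) // step + 1


def windowed_training_metrics(
    trials: Sequence[TrialRecord], window: int = 50, step: int = 5
) -> WindowSeries:
    """Running regression analysis of a training session (azimuth channel).

    For each fully contained window of ``window`` consecutive trials
    (shifted by ``step``), fits the azimuth stimulus–response regression and
    records gain, r², MAE, and the window-mean reaction time.  Centers are
    the mean trial index of each window.
    """
    trials = list(trials)
    n = len(trials)
    if n < window:
        raise ValueError(f"need at least {window} trials for one window, got {n}")
    idx = [t.trial_index for t in trials]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValueError("trials must be sorted by trial_index")

    m = n_windows(n, window, step)
    centers = np.empty(m)
    gain = np.empty(m)
    r2 = np.empty(m)
    mae = np.empty(m)
    rt = np.full(m, np.nan)
    counts = np.full(m, window, dtype=int)
    for k in range(m):
        chunk = trials[k * step: k * step + window]
        fit = fit_stimulus_response(
            [t.target.azimuth_deg for t in chunk],
            [t.response.azimuth_deg for t in chunk],
        )
        centers[k] = float(np.mean([t.trial_index for t in chunk]))
        gain[k] = fit.gain
        r2[k] = fit.r2
        mae[k] = fit.mae_deg
        rts = [t.reaction_time_ms for t in chunk if t.reaction_time_ms is not None]
        if rts:
            rt[k] = float(np.mean(rts))
    return WindowSeries(
        centers=centers, window_size=window, step=step, min_count=window,
        gain=gain, r2=r2, mae_deg=mae, rt_ms=rt, counts=counts,
    )


def local_elevation_gain(
    trials: Sequence[TrialRecord],
    bin_width_deg: float = 20.0,
    step_deg: float = 5.0,
    range_deg: tuple[float, float] = (-80.0, 60.0),
    min_count: int = 5,
) -> WindowSeries:
    """Elevation gain as a function of target azimuth.

    Bins of ``bin_width_deg`` are centred on ``range_deg[0] … range_deg[1]``
    in ``step_deg`` steps; membership uses the *target* azimuth with an
    inclusive left edge and exclusive right edge.  Bins with fewer than
    ``min_count`` trials yield NaN.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial table")
    t_az = np.array([t.target.azimuth_deg for t in trials])
    t_el = np.array([t.target.elevation_deg for t in trials])
    r_el = np.array([t.response.elevation_deg for t in trials])

    lo, hi = range_deg
    m = int(round((hi - lo) / step_deg)) + 1
    centers = lo + step_deg * np.arange(m)
    half = bin_width_deg / 2.0
    gain = np.full(m, np.nan)
    r2 = np.full(m, np.nan)
    mae = np.full(m, np.nan)
    counts = np.zeros(m, dtype=int)
    for k, c in enumerate(centers):
        mask = (t_az >= c - half) & (t_az < c + half)
        counts[k] = int(mask.sum())
        if counts[k] < min_count or t_el[mask].std() == 0:
            continue
        fit = fit_stimulus_response(t_el[mask], r_el[mask])
        gain[k] = fit.gain
        r2[k] = fit.r2
        mae[k] = fit.mae_deg
    return WindowSeries(
        centers=centers, window_size=bin_width_deg, step=step_deg,
        min_count=min_count, gain=gain, r2=r2, mae_deg=mae, counts=counts,
    )


def aggregate_series(series: Sequence[WindowSeries]) -> pd.DataFrame:
    """Mean ± SD across sessions of per-session series on a common grid.

    Sessions missing a window/bin (NaN) are excluded from that entry's
    statistics.  All series must share identical centers.
    """
    series = list(series)
    if not series:
        raise ValueError("no series to aggregate")
    centers = series[0].centers
    for s in series[1:]:
        if not np.array_equal(s.centers, centers):
            raise ValueError("series centers differ; cannot aggregate")
    out = {"center": centers}
    for name in ("gain", "r2", "mae_deg", "rt_ms"):
        if all(getattr(s, name) is not None for s in series):
            stack = np.vstack([getattr(s, name) for s in series])
            cnt = np.sum(~np.isnan(stack), axis=0)
            safe = np.maximum(cnt, 1)
            mean = np.where(cnt > 0, np.nansum(stack, axis=0) / safe, np.nan)
            var = np.where(
                cnt > 0,
                np.nansum(stack**2, axis=0) / safe - mean**2,
                np.nan,
            )
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = np.sqrt(np.clip(var, 0.0, None))
            out[f"{name}_n"] = cnt
    return pd.DataFrame(out)
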