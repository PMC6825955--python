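"""End-to-end experiment pipeline: simulate → fit → dynamics → report.

:func:`run_experiment` realizes the two-day plugging/training protocol on a
synthetic listener: a plugged pre-adaptation test, a 500-trial feedback
training block with trial-by-trial prior updating, and a plugged
post-adaptation test.  It writes the trial tables, all regression fits, the
windowed/binned dynamics series, and a pre/post comparison report including
the one-sided sign test over the regression-parameter improvements.

All artifacts are deterministic under a fixed seed: re-running with the same
configuration yields byte-identical CSV/JSON files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from . import __version__
from .config import config_hash, default_config, model_from_config, schedule_from_config
from .dynamics import local_elevation_gain, windowed_training_metrics, WindowSeries
from .io import write_trial_table
from .listener import ListenerCondition, simulate_session
from .regression import (
    CollinearityError,
    fit_azimuth_cues,
    fit_elevation_cues,
    fit_stimulus_response,
)
from .trials import TrialRecord

__all__ = ["sign_test", "compare_pre_post", "run_experiment", "PipelineError"]

logger = logging.getLogger("monaural_adapt")

#: Direction of "improvement" per regression parameter: gain and r² should
#: move up from pre to post, |bias| and MAE down.
IMPROVEMENT_UP = ("gain", "r2")
IMPROVEMENT_DOWN = ("abs_bias_deg", "mae_deg")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def sign_test(improvements: int, total: int) -> float:
    """Exact one-sided binomial tail: P(X >= improvements), X ~ Bin(total, ½)."""
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if not 0 <= improvements <= total:
        raise ValueError(
            f"improvements must be in [0, {total}], got {improvements}"
        )
    return float(sps.binom.sf(improvements - 1, total, 0.5))


def _eq1_summary(trials: Sequence[TrialRecord], component: str) -> dict:
    if component == "azimuth":
        fit = fit_stimulus_response(
            [t.target.azimuth_deg for t in trials],
            [t.response.azimuth_deg for t in trials],
        )
    else:
        fit = fit_stimulus_response(
            [t.target.elevation_deg for t in trials],
            [t.response.elevation_deg for t in trials],
        )
    d = fit.to_dict()
    d["abs_bias_deg"] = abs(fit.bias_deg)
    return d


def _by_level(trials: Sequence[TrialRecord]) -> dict[float, list[TrialRecord]]:
    out: dict[float, list[TrialRecord]] = {}
    for t in trials:
        out.setdefault(t.level_dBA, []).append(t)
    return {k: out[k] for k in sorted(out)}


def compare_pre_post(
    pre: Sequence[TrialRecord],
    post: Sequence[TrialRecord],
    hse_db: float = 10.0,
) -> dict:
    """Pre- vs post-training comparison with the sign-test summary.

    Per stimulus level, the azimuth stimulus–response parameters (gain,
    |bias|, r², MAE) are compared pre vs post; an improvement is a move
    above the pre/post diagonal for gain and r², below it for |bias| and
    MAE.  The pooled counts feed an exact one-sided sign test.  Cue-weight
    regressions (azimuth model pooled; elevation model per hemifield) are
    reported alongside.
    """
    levels_pre = _by_level(pre)
    levels_post = _by_level(post)
    shared = [lv for lv in levels_pre if lv in levels_post]
    if not shared:
        raise ValueError("pre and post sessions share no stimulus level")

    per_level: dict[str, Any] = {}
    n_improved = 0
    n_total = 0
    for lv in shared:
        fit_pre = _eq1_summary(levels_pre[lv], "azimuth")
        fit_post = _eq1_summary(levels_post[lv], "azimuth")
        improved = {}
        for param in IMPROVEMENT_UP:
            improved[param] = bool(fit_post[param] > fit_pre[param])
        for param in IMPROVEMENT_DOWN:
            improved[param] = bool(fit_post[param] < fit_pre[param])
        n_improved += sum(improved.values())
        n_total += len(improved)
        per_level[f"{lv:g}"] = {
            "pre": fit_pre, "post": fit_post, "improved": improved,
        }

    azimuth_cues = {
        "pre": fit_azimuth_cues(pre, hse_db).to_dict(),
        "post": fit_azimuth_cues(post, hse_db).to_dict(),
    }
    elevation_cues: dict[str, Any] = {}
    for epoch, trials in (("pre", pre), ("post", post)):
        elevation_cues[epoch] = {}
        for hemi in ("all", "left", "right"):
            try:
                elevation_cues[epoch][hemi] = fit_elevation_cues(
                    trials, hse_db, hemifield=hemi
                ).to_dict()
            except (ValueError, CollinearityError) as exc:
                elevation_cues[epoch][hemi] = {"error": str(exc)}

    return {
        "levels": per_level,
        "azimuth_cues": azimuth_cues,
        "elevation_cues": elevation_cues,
        "sign_test": {
            "improvements": n_improved,
            "total": n_total,
            "p_value": sign_test(n_improved, n_total),
        },
    }


def _stage_seeds(seed: int) -> dict[str, int]:
    # stable per-stage integer seeds derived from the master seed
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("pre_test", "training", "post_test", "control")
    return {name: int(s) % 2**31 for name, s in zip(names, state)}


def _series_rows(name: str, series: WindowSeries) -> list[dict]:
    frame = series.to_frame()
    rows = []
    for rec in frame.to_dict(orient="records"):
        row = {"analysis": name}
        row.update(rec)
        rows.append(row)
    return rows


def _write_dynamics_csv(path: Path, rows: list[dict]) -> None:
    cols = ["analysis", "center", "gain", "r2", "mae_deg", "rt_ms", "n"]
    lines = [",".join(cols)]
    for row in rows:
        cells = []
        for c in cols:
            v = row.get(c, "")
            if isinstance(v, float):
                cells.append("" if np.isnan(v) else f"{v:.6f}")
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_json(path: Path, obj: Mapping[str, Any]) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def _sanitize(obj):
    # JSON cannot carry NaN; report them as nulls
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_experiment(
    config: Optional[Mapping[str, Any]] = None,
    out_dir: Union[str, Path] = "experiment_out",
) -> Path:
    """Run the full synthetic experiment and write all artifacts.

    Writes ``pre_test.csv``, ``training.csv``, ``post_test.csv``,
    ``fits.json``, ``dynamics.csv``, ``report.json`` and a plain-text
    ``summary.txt`` into ``out_dir``.  Deterministic for a fixed config.
    """
    cfg = dict(default_config()) if config is None else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    hse_db = float(cfg.get("hse_db", 10.0))
    seeds = _stage_seeds(seed)
    models_cfg = cfg.get("models", {})
    design_cfg = cfg.get("design", {})
    n_test = int(design_cfg.get("n_test_trials", 180))

    def stage(name: str, fn):
        logger.info("stage %s: starting (seed %d)", name, seeds.get(name, seed))
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return result

    schedule = schedule_from_config(cfg.get("training"))
    model_pre = model_from_config("plugged_pre", models_cfg.get("plugged_pre"))
    # post model: the pre model with the schedule's end-point priors
    post_overrides = models_cfg.get("plugged_post", {})
    model_post = model_from_config("plugged_post", post_overrides)
    if not post_overrides:
        # the post-test listener is the trained state reached at the final
        # training trial (not the schedule's asymptote)
        az_prior, el_prior = schedule.prior_at(schedule.n_trials)
        model_post = replace(
            model_pre,
            condition=ListenerCondition.PLUGGED_POST,
            azimuth_prior=az_prior,
            elevation_prior=el_prior,
            perceived_ild_bias_deg=az_prior.mean_deg,
            azimuth_sensory_sd_deg=schedule.azimuth_sensory_sd_at(
                schedule.n_trials
            ),
        )

    pre_trials = stage(
        "pre_test",
        lambda: simulate_session(
            model_pre, "pre_test", seeds["pre_test"], n_trials=n_test
        ),
    )
    training_trials = stage(
        "training",
        lambda: simulate_session(
            model_pre, "training", seeds["training"], schedule=schedule
        ),
    )
    post_trials = stage(
        "post_test",
        lambda: simulate_session(
            model_post, "post_test", seeds["post_test"], n_trials=n_test
        ),
    )
    logger.info(
        "simulated %d pre, %d training, %d post trials",
        len(pre_trials), len(training_trials), len(post_trials),
    )

    write_trial_table(pre_trials, out / "pre_test.csv")
    write_trial_table(training_trials, out / "training.csv")
    write_trial_table(post_trials, out / "post_test.csv")

    def all_fits():
        fits: dict[str, Any] = {}
        for epoch, trials in (("pre", pre_trials), ("post", post_trials)):
            fits[epoch] = {
                "azimuth_by_level": {
                    f"{lv:g}": _eq1_summary(sub, "azimuth")
                    for lv, sub in _by_level(trials).items()
                },
                "elevation_by_level": {
                    f"{lv:g}": _eq1_summary(sub, "elevation")
                    for lv, sub in _by_level(trials).items()
                },
                "azimuth_cues": fit_azimuth_cues(trials, hse_db).to_dict(),
                "elevation_cues": {
                    hemi: fit_elevation_cues(trials, hse_db, hemifield=hemi).to_dict()
                    for hemi in ("all", "left", "right")
                },
            }
        return fits

    fits = stage("fit", all_fits)
    _write_json(out / "fits.json", _sanitize(fits))

    def all_dynamics():
        rows: list[dict] = []
        rows += _series_rows(
            "training_window", windowed_training_metrics(training_trials)
        )
        rows += _series_rows("local_gain_pre", local_elevation_gain(pre_trials))
        rows += _series_rows("local_gain_post", local_elevation_gain(post_trials))
        return rows

    dyn_rows = stage("dynamics", all_dynamics)
    _write_dynamics_csv(out / "dynamics.csv", dyn_rows)

    report = stage(
        "report", lambda: compare_pre_post(pre_trials, post_trials, hse_db)
    )
    report["provenance"] = {
        "config_sha256": config_hash(cfg),
        "seed": seed,
        "stage_seeds": seeds,
        "package_version": __version__,
        "n_trials": {
            "pre_test": len(pre_trials),
            "training": len(training_trials),
            "post_test": len(post_trials),
        },
    }
    _write_json(out / "report.json", _sanitize(report))

    st = report["sign_test"]
    az = report["azimuth_cues"]
    summary = [
        "monaural-adapt experiment summary",
        f"seed: {seed}   config: {report['provenance']['config_sha256'][:12]}",
        f"trials: pre {len(pre_trials)}, training {len(training_trials)}, "
        f"post {len(post_trials)}",
        f"azimuth cue weights pre:  p={az['pre']['p']:+.3f} q={az['pre']['q']:+.3f}",
        f"azimuth cue weights post: p={az['post']['p']:+.3f} q={az['post']['q']:+.3f}",
        f"sign test: {st['improvements']}/{st['total']} parameters improved, "
        f"one-sided p = {st['p_value']:.3g}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    logger.info("experiment artifacts written to %s", out)
    return out
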