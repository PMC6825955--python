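"""YAML configuration for listener models, training schedule, and designs.

The configuration is a plain mapping (see ``configs/default_experiment.yaml``
for a commented example).  Everything is optional; omitted keys fall back to
the stock model defaults.  :func:`config_hash` gives a stable SHA-256 over
the canonicalized configuration for provenance tracking.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .listener import (
    DecisionRule,
    GaussianPrior,
    ListenerModel,
    TrainingSchedule,
)

__all__ = [
    "default_config",
    "load_config",
    "merge_config",
    "config_hash",
    "model_from_config",
    "schedule_from_config",
]

_MODEL_FACTORIES = {
    "binaural": ListenerModel.binaural,
    "plugged_pre": ListenerModel.plugged_pre,
    "plugged_post": ListenerModel.plugged_post,
    "ideal": ListenerModel.ideal,
}

_PRIOR_FIELDS = ("azimuth_prior", "elevation_prior")
_SCHEDULE_PRIOR_FIELDS = (
    "azimuth_prior_start",
    "azimuth_prior_end",
    "elevation_prior_start",
    "elevation_prior_end",
)


def default_config() -> dict:
    """The built-in experiment configuration (all stock model defaults)."""
    return {
        "seed": 0,
        "hse_db": 10.0,
        "design": {
            "n_test_trials": 180,
            "n_control_trials": 300,
        },
        "models": {
            "plugged_pre": {},
            "plugged_post": {},
            "binaural": {},
        },
        "training": {
            "n_trials": 500,
        },
    }


def load_config(path: Union[str, Path, None]) -> dict:
    """Load a YAML config file merged over the defaults; ``None`` → defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(cfg, user)


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursive dict merge; override wins on scalar conflicts."""
    out = copy.deepcopy(dict(base))
    for key, val in override.items():
        if (
            key in out
            and isinstance(out[key], Mapping)
            and isinstance(val, Mapping)
        ):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def config_hash(config: Mapping[str, Any]) -> str:
    """SHA-256 of the canonical (sorted-keys) JSON form of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def _coerce_prior(value: Any) -> GaussianPrior:
    if isinstance(value, GaussianPrior):
        return value
    if isinstance(value, Mapping):
        sd = value["sd_deg"]
        sd = float("inf") if sd in ("inf", ".inf") else float(sd)
        return GaussianPrior(float(value["mean_deg"]), sd)
    raise ValueError(f"cannot interpret prior specification: {value!r}")


def model_from_config(
    name: str, overrides: Optional[Mapping[str, Any]] = None
) -> ListenerModel:
    """Build a listener model from a stock configuration name plus overrides.

    ``name`` is one of ``binaural``, ``plugged_pre``, ``plugged_post``,
    ``ideal``.  Overrides use field names of :class:`ListenerModel`; priors
    are mappings with ``mean_deg``/``sd_deg`` and the decision rule a string.
    """
    if name not in _MODEL_FACTORIES:
        raise ValueError(
            f"unknown model '{name}'; expected one of {sorted(_MODEL_FACTORIES)}"
        )
    kw = dict(overrides or {})
    for field in _PRIOR_FIELDS:
        if field in kw:
            kw[field] = _coerce_prior(kw[field])
    if "decision_rule" in kw:
        kw["decision_rule"] = DecisionRule(kw["decision_rule"])
    return _MODEL_FACTORIES[name](**kw)


def schedule_from_config(
    overrides: Optional[Mapping[str, Any]] = None,
) -> TrainingSchedule:
    kw = dict(overrides or {})
    for field in _SCHEDULE_PRIOR_FIELDS:
        if field in kw:
            kw[field] = _coerce_prior(kw[field])
    return TrainingSchedule(**kw)
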