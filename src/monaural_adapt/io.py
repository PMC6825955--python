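"""CSV trial-table reading and writing.

The on-disk contract is a UTF-8 comma-separated file with the exact header

    trial_index,phase,condition,stimulus_type,level_dBA,target_az_deg,target_el_deg,resp_az_deg,resp_el_deg,rt_ms

Angles are decimal degrees; ``rt_ms`` may be empty (missing reaction time).
Numeric fields are written with 6 decimal places so that write→read
round-trips are exact to 1e-6 and repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .trials import (
    Condition,
    DoublePolarDirection,
    Phase,
    StimulusType,
    TrialRecord,
)

__all__ = ["TRIAL_TABLE_COLUMNS", "read_trial_table", "write_trial_table"]

TRIAL_TABLE_COLUMNS = (
    "trial_index",
    "phase",
    "condition",
    "stimulus_type",
    "level_dBA",
    "target_az_deg",
    "target_el_deg",
    "resp_az_deg",
    "resp_el_deg",
    "rt_ms",
)


class TrialTableError(ValueError):
    """Malformed trial table (bad header, token, or numeric field)."""


def _parse_enum(enum_cls, token: str, row: int, column: str):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise TrialTableError(
            f"row {row}, column '{column}': unknown token '{token}' "
            f"(expected one of: {valid})"
        ) from None


def _parse_float(value, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TrialTableError(
            f"row {row}, column '{column}': non-numeric value '{value}'"
        ) from None


def read_trial_table(path: Union[str, Path]) -> list[TrialRecord]:
    """Read a trial table CSV into a list of :class:`TrialRecord`.

    Raises :class:`TrialTableError` naming the row (1-based, excluding the
    header) and column for any missing column, unknown enum token, or
    non-numeric angle/level.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing column(s): {', '.join(missing)}")

    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda col: getattr(row, col)  # noqa: E731
        rt_raw = get("rt_ms").strip()
        records.append(
            TrialRecord(
                trial_index=int(_parse_float(get("trial_index"), i, "trial_index")),
                phase=_parse_enum(Phase, get("phase"), i, "phase"),
                condition=_parse_enum(Condition, get("condition"), i, "condition"),
                stimulus_type=_parse_enum(
                    StimulusType, get("stimulus_type"), i, "stimulus_type"
                ),
                level_dBA=_parse_float(get("level_dBA"), i, "level_dBA"),
                target=DoublePolarDirection(
                    _parse_float(get("target_az_deg"), i, "target_az_deg"),
                    _parse_float(get("target_el_deg"), i, "target_el_deg"),
                ),
                response=DoublePolarDirection(
                    _parse_float(get("resp_az_deg"), i, "resp_az_deg"),
                    _parse_float(get("resp_el_deg"), i, "resp_el_deg"),
                ),
                reaction_time_ms=(
                    _parse_float(rt_raw, i, "rt_ms") if rt_raw else None
                ),
            )
        )
    return records


def write_trial_table(trials: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write trials to CSV with the canonical header and 6-decimal numerics."""
    lines = [",".join(TRIAL_TABLE_COLUMNS)]
    for t in trials:
        rt = "" if t.reaction_time_ms is None else f"{t.reaction_time_ms:.6f}"
        lines.append(
            f"{t.trial_index},{t.phase.value},{t.condition.value},"
            f"{t.stimulus_type.value},{t.level_dBA:.6f},"
            f"{t.target.azimuth_deg:.6f},{t.target.elevation_deg:.6f},"
            f"{t.response.azimuth_deg:.6f},{t.response.elevation_deg:.6f},{rt}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
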