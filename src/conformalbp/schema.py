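"""Column schema shared by the cohort generator and the data layer.

A *measurement record* is one timestamped ambulatory observation: the seven
wearable-derived physiological features, the day/night phase, and the
oscillometric reference SBP/DBP in mmHg. Records live in a pandas DataFrame
with exactly these columns, in this order.
"""

from __future__ import annotations

#: The seven model features, in canonical column order.
FEATURES: tuple[str, ...] = (
    "arm_angle",    # degrees, arm posture relative to the reference line
    "beat_length",  # ms, PPG cardiac-cycle length
    "dpdt",         # a.u./s, PPG maximum-slope point
    "heart_rate",   # bpm
    "hrv",          # ms, beat-to-beat interval variability
    "quality",      # PPG signal-quality score in [0, 1]
    "rpat",         # ms, ECG R-peak to radial-pulse arrival delay
)

#: Reference (target) columns.
TARGETS: tuple[str, ...] = ("sbp_ref", "dbp_ref")

#: Full feature-table column order.
COLUMNS: tuple[str, ...] = (
    "subject_id",
    "timestamp",
    "phase",
    *FEATURES,
    *TARGETS,
    "valid",
)

DAYTIME = "daytime"
NIGHTTIME = "nighttime"
PHASES = (DAYTIME, NIGHTTIME)

#: Map short target names to reference columns.
TARGET_COLUMNS = {"sbp": "sbp_ref", "dbp": "dbp_ref"}


def target_column(target: str) -> str:
    """Resolve ``"sbp"``/``"dbp"`` to its reference column name."""
    try:
        return TARGET_COLUMNS[target.lower()]
    except KeyError:
        raise ValueError(f"unknown target {target!r}; expected 'sbp' or 'dbp'") from None
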