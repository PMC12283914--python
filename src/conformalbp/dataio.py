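"""Feature-table I/O, temporal preprocessing, and subject-level splits.

The preprocessing mirrors the ambulatory-protocol balancing rules: daytime
readings arrive every 30 min but nighttime readings only hourly, so daytime
hours are downsampled to their first valid reading (falling back to the
second when the first is invalid) and remaining blank hourly slots are
forward-filled from the most recent reading. The result is an equal hourly
sampling density day and night, so the day/night sample sizes in the train,
calibration, and test sets are consistent.

Splits are by *subject* (never by record, which would leak subjects across
sets) into 60% train / 24% calibration / 16% test, repeated with
independent random permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import COLUMNS, DAYTIME, FEATURES, NIGHTTIME, TARGETS

logger = logging.getLogger(__name__)

_NUMERIC = list(FEATURES) + list(TARGETS)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV into the canonical schema.

    Rows with unparseable or missing numeric cells are flagged
    ``valid=False`` rather than dropped (the count is logged); a missing
    mandatory column or an unparseable timestamp raises.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c != "valid" and c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory columns: {missing}")
    if "valid" not in df.columns:
        df["valid"] = True
    if len(df) == 0:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return df[list(COLUMNS)]

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        bad = df.loc[ts.isna(), "timestamp"].iloc[0]
        raise ValueError(f"unparseable timestamp: {bad!r}")
    df["timestamp"] = ts

    ok = df["valid"].astype(bool)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        ok &= df[col].notna()
    ok &= df["phase"].isin([DAYTIME, NIGHTTIME])
    n_flagged = int((df["valid"].astype(bool) & ~ok).sum())
    if n_flagged:
        logger.info("read_feature_table: flagged %d rows invalid on type checks", n_flagged)
    df["valid"] = ok
    df = df.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(drop=True)
    return df[list(COLUMNS)]


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write records as UTF-8 CSV with ISO-8601 timestamps."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# -- temporal preprocessing -------------------------------------------------


def downsample_daytime(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one daytime record per subject per clock hour.

    The first *valid* measurement of the hour represents it; when the first
    is invalid the later one is selected. Hours with no valid measurement
    yield no record (left for :func:`impute_forward_fill`). Nighttime
    records pass through unchanged. Hour buckets align to on-the-hour clock
    times of the record timestamps.
    """
    day = records[records["phase"] == DAYTIME]
    night = records[records["phase"] == NIGHTTIME]
    day = day[day["valid"].astype(bool)]
    day = day.sort_values(["subject_id", "timestamp"], kind="stable")
    hour = day["timestamp"].dt.floor("h")
    day = day.loc[~pd.DataFrame({"s": day["subject_id"], "h": hour}).duplicated()]
    out = pd.concat([day, night]).sort_values(
        ["subject_id", "timestamp"], kind="stable"
    )
    return out.reset_index(drop=True)


def impute_forward_fill(records: pd.DataFrame) -> pd.DataFrame:
    """Fill blank hourly slots with a copy of the previous record.

    Builds the cohort-wide hourly grid (so every subject ends with the same
    slot count per phase), places each subject's valid records on it, and
    copies the most recent preceding record into empty or invalid slots,
    updating its timestamp to the slot time. A leading blank slot is
    back-filled from the first available record. A subject with zero valid
    records is an error.
    """
    if len(records) == 0:
        raise ValueError("no records to impute")
    ts = pd.to_datetime(records["timestamp"])
    grid = pd.date_range(ts.min().floor("h"), ts.max().floor("h"), freq="h")
    pieces = []
    for subject, group in records.groupby("subject_id", sort=True):
        g = group[group["valid"].astype(bool)].sort_values("timestamp", kind="stable")
        if len(g) == 0:
            raise ValueError(f"subject {subject!r} has no valid records to fill from")
        g = g.copy()
        g["__slot"] = g["timestamp"].dt.floor("h")
        g = g.drop_duplicates("__slot", keep="first").set_index("__slot")
        # valid/subject_id are reassigned below; excluding them from the
        # fill keeps every filled column numeric.
        g = g.drop(columns=["valid", "subject_id", "phase"])
        g = g.reindex(grid).ffill().bfill()
        g["timestamp"] = grid
        g["subject_id"] = subject
        g["valid"] = True
        pieces.append(g.reset_index(drop=True))
    out = pd.concat(pieces, ignore_index=True)
    out["phase"] = phase_of(out["timestamp"])
    return out[list(COLUMNS)]


def phase_of(timestamps: pd.Series, day_window: tuple[int, int] = (8, 20)) -> pd.Series:
    """Phase labels from clock time, half-open daytime window [start, end)."""
    hours = pd.to_datetime(timestamps).dt.hour
    return pd.Series(
        np.where((hours >= day_window[0]) & (hours < day_window[1]), DAYTIME, NIGHTTIME),
        index=timestamps.index,
    )


def preprocess(records: pd.DataFrame) -> pd.DataFrame:
    """Downsample daytime hours, then forward-fill the hourly grid."""
    return impute_forward_fill(downsample_daytime(records))


# -- splits -----------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """One random subject-level 60/24/16 partition."""

    repeat_index: int
    train_subjects: tuple[str, ...]
    calibration_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        sets = (set(self.train_subjects), set(self.calibration_subjects),
                set(self.test_subjects))
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split sets must be disjoint")

    def subset(self, records: pd.DataFrame, which: str) -> pd.DataFrame:
        ids = getattr(self, f"{which}_subjects")
        return records[records["subject_id"].isin(ids)]


def make_split_plans(subject_ids, n_repeats: int = 5, seed: int = 0) -> list[SplitPlan]:
    """Repeated random 60/24/16 subject partitions, deterministic given seed.

    Rounding: train gets ``floor(0.6 n)``, calibration ``floor`` of 60% of
    the remainder, test the rest. This is repeated random splitting (the
    sets are redrawn independently each repeat), not a 5-way partition.
    """
    subjects = sorted(map(str, set(subject_ids)))
    n = len(subjects)
    if n < 10:
        raise ValueError(f"need at least 10 subjects to split, got {n}")
    n_train = int(np.floor(0.6 * n))
    n_cal = int(np.floor(0.6 * (n - n_train)))
    n_test = n - n_train - n_cal
    if min(n_train, n_cal, n_test) < 1:
        raise ValueError("too few subjects to populate train/calibration/test")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, n_repeats + 1):
        perm = rng.permutation(subjects)
        plans.append(SplitPlan(
            repeat_index=rep,
            train_subjects=tuple(perm[:n_train]),
            calibration_subjects=tuple(perm[n_train:n_train + n_cal]),
            test_subjects=tuple(perm[n_train + n_cal:]),
            seed=seed,
        ))
    return plans


def save_split_plans(plans: list[SplitPlan], path) -> None:
    """Serialise split plans to JSON for reproducibility."""
    payload = [
        {
            "repeat_index": p.repeat_index,
            "train_subjects": list(p.train_subjects),
            "calibration_subjects": list(p.calibration_subjects),
            "test_subjects": list(p.test_subjects),
            "seed": p.seed,
        }
        for p in plans
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_split_plans(path) -> list[SplitPlan]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        SplitPlan(
            repeat_index=d["repeat_index"],
            train_subjects=tuple(d["train_subjects"]),
            calibration_subjects=tuple(d["calibration_subjects"]),
            test_subjects=tuple(d["test_subjects"]),
            seed=d["seed"],
        )
        for d in payload
    ]
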