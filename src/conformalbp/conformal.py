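"""Split conformal calibration of raw quantile bands.

Conformalised quantile regression: on a held-out calibration set, score
each record by the signed distance from its reference value to the nearest
raw band edge, ``s = max(lower - y, y - upper)`` (negative iff the value
lies strictly inside the band). The conformal threshold ``q_hat`` is the
``ceil((n+1)(1-alpha))``-th order statistic of the n calibration scores;
expanding both band edges by ``q_hat`` yields intervals whose marginal
coverage over exchangeable draws is guaranteed to lie in
``[1-alpha, 1-alpha + 1/(n+1)]``. ``q_hat`` may be negative (the raw band
over-covers and is shrunk) or, when the calibration set is too small for
the requested rank, an infinite sentinel flagging unbounded intervals.

Calibration can be stratified by day/night phase — nocturnal BP is more
variable, so nighttime thresholds are systematically larger — or pooled,
which is the setting in which the exchangeability guarantee is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import PHASES, target_column

#: Phase label for unstratified calibration.
POOLED = "pooled"

# Guard against binary-float rank inflation: (n+1)*(1-alpha) can land an
# ulp above an exact integer (e.g. 20*0.9 = 18.000000000000004), which
# would wrongly bump the order statistic by one.
_RANK_EPS = 1e-9


@dataclass(frozen=True)
class ConformalCalibration:
    """A fitted conformal threshold for one (target, phase, alpha) cell."""

    target: str
    phase: str
    alpha: float
    q_hat: float
    n_calibration: int

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.q_hat)

    def to_dict(self) -> dict:
        return {
            "target": self.target, "phase": self.phase, "alpha": self.alpha,
            "q_hat": self.q_hat, "n_calibration": self.n_calibration,
        }


def conformity_score(lower, upper, y) -> np.ndarray:
    """Signed distance from reference values to the nearest band edge.

    Positive = the raw band missed the value; negative = inside, by the
    margin to the nearer edge.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.maximum(lower - y, y - upper)


def conformal_quantile(scores, alpha: float) -> float:
    """The ``ceil((n+1)(1-alpha))``-th order statistic of the scores.

    Returns ``+inf`` when the rank exceeds n (calibration set too small to
    support the requested error rate at finite width).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty calibration score set")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = scores.size
    k = math.ceil((n + 1) * (1.0 - alpha) - _RANK_EPS)
    if k > n:
        return math.inf
    return float(np.sort(scores)[k - 1])


def calibrate(calibration_rows: pd.DataFrame, triples: pd.DataFrame,
              target: str, alpha: float, phase: str = POOLED) -> ConformalCalibration:
    """Compute the conformal threshold for one (target, phase, alpha) cell.

    ``triples`` must be row-aligned with ``calibration_rows`` (same index)
    and carry ``lower``/``upper`` columns from :func:`~conformalbp.qboost.predict_triple`.
    """
    if phase not in (*PHASES, POOLED):
        raise ValueError(f"unknown phase {phase!r}")
    rows = calibration_rows
    bands = triples
    if phase != POOLED:
        mask = rows["phase"] == phase
        rows = rows[mask]
        bands = bands.loc[rows.index]
    y = rows[target_column(target)].to_numpy()
    scores = conformity_score(bands["lower"].to_numpy(), bands["upper"].to_numpy(), y)
    return ConformalCalibration(
        target=target.lower(), phase=phase, alpha=alpha,
        q_hat=conformal_quantile(scores, alpha), n_calibration=len(scores),
    )


def apply(calibration: ConformalCalibration, triples: pd.DataFrame) -> pd.DataFrame:
    """Expand raw bands by ``q_hat`` into calibrated prediction intervals.

    Returns columns ``lo``, ``hi``, ``point``, ``alpha``, ``unbounded``.
    Negative thresholds shrink the band; intervals are not clipped at the
    point estimate.
    """
    q = calibration.q_hat
    out = pd.DataFrame({
        "lo": triples["lower"].to_numpy() - q,
        "hi": triples["upper"].to_numpy() + q,
        "point": triples["point"].to_numpy(),
    }, index=triples.index)
    out["alpha"] = calibration.alpha
    out["unbounded"] = calibration.unbounded
    if calibration.unbounded:
        out["lo"] = -math.inf
        out["hi"] = math.inf
    return out


def covers(intervals: pd.DataFrame, y) -> np.ndarray:
    """Boolean per-row coverage indicator (closed interval endpoints)."""
    y = np.asarray(y, dtype=float)
    return (intervals["lo"].to_numpy() <= y) & (y <= intervals["hi"].to_numpy())


def save_calibrations(calibrations, path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in calibrations], fh, indent=1)
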