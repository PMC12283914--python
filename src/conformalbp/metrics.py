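"""Evaluation statistics for cuffless BP estimation and its intervals.

Point-estimate accuracy follows the wearable-device validation standards:
mean absolute difference (MAD), mean error (ME), and the N-1 standard
deviation of the errors, with IEEE 1708 letter grades (Grade A requires
MAD < 5 mmHg) and the AAMI bound (|ME| <= 5 and SD <= 8 mmHg). Interval
quality is summarised by the coverage rate and the incremental
cost-effectiveness ratio (ICER), repurposed as the extra interval
half-width (mmHg) paid per percentage point of coverage gained when
tightening the error rate from alpha=0.10 to alpha=0.05::

    ICER = (q_hat_0.05 - q_hat_0.10) / (Coverage_0.05 - Coverage_0.10)

Bland-Altman agreement, the coefficient of variability (CV = SD/mean, used
to compare day vs night BP variability), Pearson correlation, and a WHO
140/90-threshold hypertension-capture check complete the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

#: WHO hypertension thresholds (mmHg).
WHO_SBP_THRESHOLD = 140.0
WHO_DBP_THRESHOLD = 90.0

#: IEEE 1708 letter-grade upper MAD bounds; only the Grade-A bound (5 mmHg)
#: is standard-printed, B/C are configurable conventions.
DEFAULT_IEEE_BOUNDARIES: tuple[tuple[str, float], ...] = (("A", 5.0), ("B", 6.0), ("C", 7.0))


def _pair(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    if est.size == 0:
        raise ValueError("empty input")
    return est, ref


def mad(est, ref) -> float:
    """Mean absolute difference (mmHg)."""
    est, ref = _pair(est, ref)
    return float(np.mean(np.abs(est - ref)))


def me_sd(est, ref) -> tuple[float, float]:
    """Mean error and N-1 standard deviation of the errors (mmHg)."""
    est, ref = _pair(est, ref)
    if est.size < 2:
        raise ValueError("need n >= 2 for the error SD")
    err = est - ref
    return float(err.mean()), float(err.std(ddof=1))


def cv(values) -> float:
    """Coefficient of variability: N-1 SD divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2")
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(values.std(ddof=1) / mean)


def coverage_rate(intervals, refs) -> float:
    """Percent of reference values inside their closed intervals."""
    refs = np.asarray(refs, dtype=float)
    lo = np.asarray([iv[0] for iv in intervals], dtype=float) if not hasattr(intervals, "columns") \
        else intervals["lo"].to_numpy()
    hi = np.asarray([iv[1] for iv in intervals], dtype=float) if not hasattr(intervals, "columns") \
        else intervals["hi"].to_numpy()
    if refs.size == 0:
        raise ValueError("empty input")
    if lo.shape != refs.shape:
        raise ValueError("intervals and refs must have equal length")
    return float(100.0 * np.mean((lo <= refs) & (refs <= hi)))


def icer(q05: float, q10: float, cov05: float, cov10: float) -> float:
    """Interval-width cost per percent of coverage between two error rates.

    ``(q_hat at alpha=0.05 minus at 0.10) / (coverage% at 0.05 minus at
    0.10)``, in mmHg per percentage point. Returns NaN when the coverage
    difference is zero (undefined trade-off).
    """
    d_cov = cov05 - cov10
    if d_cov == 0:
        return math.nan
    return (q05 - q10) / d_cov


def ieee_grade(mad_value: float,
               boundaries: Sequence[tuple[str, float]] = DEFAULT_IEEE_BOUNDARIES) -> str:
    """IEEE 1708 letter grade for a MAD value: first grade whose bound is not met -> next.

    Grade A iff MAD < 5 mmHg (strict); remaining boundaries are
    configurable, anything beyond the last bound grades 'D'.
    """
    if mad_value < 0:
        raise ValueError("MAD must be >= 0")
    for grade, bound in boundaries:
        if mad_value < bound:
            return grade
    return "D"


def aami_check(me: float, sd: float) -> bool:
    """AAMI criterion: |ME| <= 5 mmHg and SD <= 8 mmHg (non-strict)."""
    if sd < 0:
        raise ValueError("SD must be >= 0")
    return abs(me) <= 5.0 and sd <= 8.0


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 1.96-SD limits of agreement, plus per-pair plot data."""

    bias: float
    loa_lo: float
    loa_hi: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(est, ref) -> BlandAltman:
    """Bland-Altman agreement summary of estimates against reference."""
    est, ref = _pair(est, ref)
    bias, sd = me_sd(est, ref)
    return BlandAltman(
        bias=bias,
        loa_lo=bias - 1.96 * sd,
        loa_hi=bias + 1.96 * sd,
        means=(est + ref) / 2.0,
        diffs=est - ref,
    )


def pearson_r(est, ref) -> float:
    """Pearson correlation between estimates and reference values."""
    est, ref = _pair(est, ref)
    return float(stats.pearsonr(est, ref).statistic)


def residual_ttest(est, ref) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean residual = 0: (t, p)."""
    est, ref = _pair(est, ref)
    res = stats.ttest_1samp(est - ref, 0.0)
    return float(res.statistic), float(res.pvalue)


class HypertensionFlags(NamedTuple):
    """Alarm flags for one prediction interval against a BP threshold."""

    point_alarm: bool
    ref_alarm: bool
    interval_captures: bool
    missed_by_point_caught_by_interval: bool


def hypertension_capture(point: float, lo: float, hi: float, ref: float,
                         threshold: float = WHO_SBP_THRESHOLD) -> HypertensionFlags:
    """Does the interval capture a hypertensive reading the point misses?

    The clinically interesting case: the point estimate sits below the
    threshold while the true reference is above it, yet the interval's
    upper limit still reaches the threshold — the interval flags a
    condition the point estimate alone would miss.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    point_alarm = point >= threshold
    ref_alarm = ref >= threshold
    interval_captures = hi >= threshold
    return HypertensionFlags(
        point_alarm=bool(point_alarm),
        ref_alarm=bool(ref_alarm),
        interval_captures=bool(interval_captures),
        missed_by_point_caught_by_interval=bool(
            ref_alarm and not point_alarm and interval_captures
        ),
    )


@dataclass(frozen=True)
class ErrorSummary:
    """Point-estimate accuracy for one (target, phase) cell."""

    mad: float
    me: float
    sd: float
    pearson_r: float
    n: int
    phase: str
    target: str

    @property
    def ieee(self) -> str:
        return ieee_grade(self.mad)

    @property
    def aami_pass(self) -> bool:
        return aami_check(self.me, self.sd)


def error_summary(est, ref, phase: str = "24h", target: str = "sbp") -> ErrorSummary:
    """Compute MAD/ME/SD/Pearson for one slice of predictions."""
    est, ref = _pair(est, ref)
    me, sd = me_sd(est, ref)
    return ErrorSummary(
        mad=mad(est, ref), me=me, sd=sd,
        pearson_r=pearson_r(est, ref) if est.size > 2 and np.std(est) > 0 else math.nan,
        n=int(est.size), phase=phase, target=target,
    )
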