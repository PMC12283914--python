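"""Synthetic 24-h ambulatory blood-pressure cohort generator.

Emulates an ambulatory BP monitoring (ABPM) protocol: oscillometric
reference readings every 30 min during waking hours (08:00-20:00) and every
60 min at night, alongside seven wearable ECG/PPG-derived features per
reading. The generative model is the package's own and is deliberately
linear-Gaussian so that the conditional quantiles of reference BP given the
features are available in closed form (:func:`true_conditional_quantile`)
and can serve as an oracle for validating the quantile regression stack.

Reference SBP for subject *s* at schedule slot *t* decomposes as::

    sbp = pop_mean + b_s + d_s(t) + sigma(t) * z_{s,t}

where ``b_s`` is a Gaussian between-subject baseline offset, ``d_s(t)`` a
deterministic diurnal profile (circadian cosine plus a nocturnal dip,
centred over the schedule so the pooled mean is exact), and ``z`` a
standardised AR(1) within-subject process whose marginal SD ``sigma(t)`` is
inflated at night to reproduce the larger nocturnal BP variability seen in
ambulatory data. The variance budget is solved so the pooled SD equals the
configured population SD by construction. DBP shares the structure through
a fixed correlation with the SBP components, scaled to its own moments.

Features are generated from SBP via linear links with independent Gaussian
noise (rPAT strictly decreasing in SBP — standard pulse-arrival-time
physiology; dP/dt increasing; HR and HRV weakly linked; arm angle and
quality carry no BP signal; beat length is a noisy transform of HR).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .schema import COLUMNS, DAYTIME, FEATURES, NIGHTTIME

#: Clock hour of the circadian SBP peak (mid-afternoon acrophase).
ACROPHASE_HOUR = 14.0

#: SD of the between-subject resting heart-rate baseline (bpm). The
#: heart-rate feature channel's ``noise_sd`` is the *total* non-BP spread,
#: of which this subject-level share is drawn once per subject.
HR_SUBJECT_SD = 8.0

#: SD of the beat-length jitter around 60000 / heart-rate (ms).
BEAT_JITTER_SD = 5.0

#: Calendar date on which every simulated 24-h session starts.
SESSION_START = "2024-01-01"


@dataclass(frozen=True)
class FeatureChannel:
    """One linear-Gaussian feature link: ``x = intercept + slope * (sbp - pop_mean) + N(0, noise_sd^2)``."""

    intercept: float
    slope: float
    noise_sd: float


def default_feature_link() -> dict[str, FeatureChannel]:
    """Default feature links, in physiologically plausible units.

    Slopes are per mmHg of SBP deviation from the population mean. rPAT
    falls ~1 ms per mmHg around a 250 ms centre; dP/dt rises with pressure;
    heart rate and HRV carry weak partial signal; arm angle and quality are
    pure nuisance channels.
    """
    return {
        "rpat": FeatureChannel(250.0, -1.0, 10.0),
        "dpdt": FeatureChannel(1.0, 0.008, 0.15),
        "heart_rate": FeatureChannel(70.0, 0.10, math.hypot(HR_SUBJECT_SD, 5.0)),
        "hrv": FeatureChannel(50.0, -0.20, 15.0),
        "arm_angle": FeatureChannel(15.0, 0.0, 20.0),
        "quality": FeatureChannel(0.85, 0.0, 0.08),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic ambulatory cohort.

    Defaults reproduce the target population moments (SBP 123.48 +/- 20.04,
    DBP 75.80 +/- 14.47 mmHg) and the day 30-min / night 60-min ABPM
    schedule. ``between_subject_fraction`` splits the population variance
    into a between-subject baseline share and a within-subject share; the
    within-subject share is further divided between the deterministic
    diurnal profile and the AR(1) fluctuation so that the pooled variance
    equals the configured population variance by construction.
    """

    n_subjects: int = 100
    day_window: tuple[int, int] = (8, 20)
    day_interval_min: int = 30
    night_interval_min: int = 60
    sbp_pop_mean: float = 123.48
    sbp_pop_sd: float = 20.04
    dbp_pop_mean: float = 75.80
    dbp_pop_sd: float = 14.47
    sbp_dbp_corr: float = 0.7
    between_subject_fraction: float = 0.6
    nocturnal_dip: float = 10.0
    circadian_amplitude: float = 5.0
    phase_shift_sd: float = 0.5
    ar1_rho: float = 0.6
    noise_sd_night_inflation: float = 1.3
    feature_link: Mapping[str, FeatureChannel] = field(default_factory=default_feature_link)
    p_missing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        d0, d1 = self.day_window
        if not (0 <= d0 < d1 <= 24):
            raise ValueError("day_window must satisfy 0 <= start < end <= 24")
        if self.day_interval_min <= 0 or self.night_interval_min <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.sbp_pop_sd <= 0 or self.dbp_pop_sd <= 0:
            raise ValueError("population SDs must be strictly positive")
        if not 0 < self.between_subject_fraction < 1:
            raise ValueError("between_subject_fraction must lie in (0, 1)")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_sd_night_inflation < 1:
            raise ValueError("noise_sd_night_inflation must be >= 1")
        if not 0 <= self.p_missing < 1:
            raise ValueError("p_missing must lie in [0, 1)")
        if not -1 < self.sbp_dbp_corr < 1:
            raise ValueError("sbp_dbp_corr must lie in (-1, 1)")
        if self.nocturnal_dip < 0:
            raise ValueError("nocturnal_dip must be >= 0")
        # Fail fast on an infeasible variance budget.
        self._within_sd_day()

    @classmethod
    def homoscedastic(cls, **overrides) -> "CohortConfig":
        """A config whose pooled BP is exactly Gaussian and homoscedastic.

        Removes the diurnal profile and the night noise inflation so that
        :func:`true_conditional_quantile` is exact rather than
        moment-matched. Used by the oracle-based quantile-recovery tests.
        """
        overrides.setdefault("circadian_amplitude", 0.0)
        overrides.setdefault("nocturnal_dip", 0.0)
        overrides.setdefault("noise_sd_night_inflation", 1.0)
        overrides.setdefault("phase_shift_sd", 0.0)
        return cls(**overrides)

    # -- schedule -----------------------------------------------------------

    def schedule_minutes(self) -> tuple[np.ndarray, np.ndarray]:
        """Minutes since session start (08:00 by default) and phase labels.

        One 24-h session: day slots every ``day_interval_min`` within the
        day window, night slots every ``night_interval_min`` until the next
        day window opens. Phase is assigned from the half-open clock window
        ``[day_start, day_end)``.
        """
        d0, d1 = self.day_window
        day = np.arange(0, (d1 - d0) * 60, self.day_interval_min)
        night = np.arange((d1 - d0) * 60, 24 * 60, self.night_interval_min)
        minutes = np.concatenate([day, night])
        phase = np.array([DAYTIME] * len(day) + [NIGHTTIME] * len(night))
        return minutes, phase

    def n_slots(self) -> tuple[int, int]:
        """(daytime, nighttime) slot counts per subject per 24 h."""
        _, phase = self.schedule_minutes()
        return int((phase == DAYTIME).sum()), int((phase == NIGHTTIME).sum())

    # -- variance budget ----------------------------------------------------

    def _diurnal_profile(self, clock_hours: np.ndarray, is_night: np.ndarray,
                         phase_shift: float = 0.0, dip: float | None = None) -> np.ndarray:
        """Centred diurnal SBP profile at the given schedule slots (mmHg)."""
        if dip is None:
            dip = self.nocturnal_dip
        raw = self.circadian_amplitude * np.cos(
            2 * np.pi * (clock_hours - ACROPHASE_HOUR - phase_shift) / 24.0
        ) - dip * is_night
        return raw - raw.mean()

    def _schedule_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        minutes, phase = self.schedule_minutes()
        clock = (self.day_window[0] + minutes / 60.0) % 24.0
        return minutes, clock, (phase == NIGHTTIME)

    def _within_sd_day(self) -> float:
        """Daytime marginal SD of the AR(1) residual, from the variance budget.

        between + diurnal + schedule-weighted AR variance = pop variance.
        Raises if the diurnal profile already exhausts the within-subject
        share (degenerate split).
        """
        _, clock, is_night = self._schedule_arrays()
        v_diurnal = float(np.var(self._diurnal_profile(clock, is_night)))
        within = (1.0 - self.between_subject_fraction) * self.sbp_pop_sd**2
        resid = within - v_diurnal
        if resid <= 0:
            raise ValueError(
                "degenerate variance split: diurnal profile variance "
                f"({v_diurnal:.1f}) exceeds the within-subject budget ({within:.1f})"
            )
        w_night = is_night.mean()
        kappa2 = self.noise_sd_night_inflation**2
        return math.sqrt(resid / ((1 - w_night) + w_night * kappa2))


# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one 24-h ambulatory session for every subject.

    Returns a DataFrame in :data:`conformalbp.schema.COLUMNS` order, one row
    per schedule slot per subject, deterministic given ``config.seed``.
    Rows are marked ``valid=False`` with probability ``p_missing``
    (acquisition failures), mimicking the gaps the preprocessing rules must
    handle.
    """
    rng = np.random.default_rng(config.seed)
    minutes, phase = config.schedule_minutes()
    _, clock, is_night = config._schedule_arrays()
    n_slots = len(minutes)
    n = config.n_subjects

    sd_between = math.sqrt(config.between_subject_fraction) * config.sbp_pop_sd
    sd_day = config._within_sd_day()
    sigma_t = np.where(is_night, sd_day * config.noise_sd_night_inflation, sd_day)

    s = config.dbp_pop_sd / config.sbp_pop_sd
    r = config.sbp_dbp_corr

    # Between-subject baselines; redraw the rare profiles violating DBP < SBP.
    base_s = rng.normal(0.0, sd_between, size=n)
    base_d_ind = rng.normal(0.0, sd_between, size=n)
    base_d = s * (r * base_s + math.sqrt(1 - r * r) * base_d_ind)
    while True:
        bad = (config.dbp_pop_mean + base_d) >= (config.sbp_pop_mean + base_s)
        if not bad.any():
            break
        k = int(bad.sum())
        base_s[bad] = rng.normal(0.0, sd_between, size=k)
        base_d[bad] = s * (r * base_s[bad] + math.sqrt(1 - r * r) * rng.normal(0.0, sd_between, size=k))

    phase_shift = rng.normal(0.0, config.phase_shift_sd, size=n)
    hr_baseline = config.feature_link["heart_rate"].intercept + rng.normal(0.0, HR_SUBJECT_SD, size=n)

    # Standardised AR(1) processes (unit marginal variance), one pair per subject.
    rho = config.ar1_rho
    innov_scale = math.sqrt(1 - rho * rho)

    def ar1_paths(count: int) -> np.ndarray:
        z = np.empty((count, n_slots))
        z[:, 0] = rng.normal(0.0, 1.0, size=count)
        for t in range(1, n_slots):
            z[:, t] = rho * z[:, t - 1] + innov_scale * rng.normal(0.0, 1.0, size=count)
        return z

    z_s = ar1_paths(n)
    z_d = r * z_s + math.sqrt(1 - r * r) * ar1_paths(n)

    diurnal = np.stack([
        config._diurnal_profile(clock, is_night, phase_shift=phase_shift[i])
        for i in range(n)
    ])

    sbp = config.sbp_pop_mean + base_s[:, None] + diurnal + sigma_t[None, :] * z_s
    dbp = config.dbp_pop_mean + base_d[:, None] + s * diurnal + s * sigma_t[None, :] * z_d

    sbp_dev = (sbp - config.sbp_pop_mean).ravel()
    total = n * n_slots
    link = config.feature_link

    def channel(name: str, noise_sd: float | None = None, offset: np.ndarray | float = 0.0) -> np.ndarray:
        ch = link[name]
        sd = ch.noise_sd if noise_sd is None else noise_sd
        base = ch.intercept if np.isscalar(offset) and offset == 0.0 else offset
        return base + ch.slope * sbp_dev + rng.normal(0.0, sd, size=total)

    rpat = channel("rpat")
    dpdt = channel("dpdt")
    hr_record_sd = math.sqrt(max(link["heart_rate"].noise_sd**2 - HR_SUBJECT_SD**2, 1.0))
    heart_rate = channel(
        "heart_rate", noise_sd=hr_record_sd,
        offset=np.repeat(hr_baseline, n_slots),
    )
    heart_rate = np.clip(heart_rate, 30.0, None)
    hrv = channel("hrv")
    arm_angle = channel("arm_angle")
    quality = np.clip(channel("quality"), 0.0, 1.0)
    beat_length = 60000.0 / heart_rate + rng.normal(0.0, BEAT_JITTER_SD, size=total)

    valid = rng.random(total) >= config.p_missing

    start = pd.Timestamp(f"{SESSION_START} {config.day_window[0]:02d}:00")
    timestamps = start + pd.to_timedelta(np.tile(minutes, n), unit="m")

    frame = pd.DataFrame({
        "subject_id": np.repeat([f"S{i:04d}" for i in range(n)], n_slots),
        "timestamp": timestamps,
        "phase": np.tile(phase, n),
        "arm_angle": arm_angle,
        "beat_length": beat_length,
        "dpdt": dpdt,
        "heart_rate": heart_rate,
        "hrv": hrv,
        "quality": quality,
        "rpat": rpat,
        "sbp_ref": sbp.ravel(),
        "dbp_ref": dbp.ravel(),
        "valid": valid,
    })
    return frame[list(COLUMNS)]


# ---------------------------------------------------------------------------


def conditional_posterior(config: CohortConfig, features: Mapping[str, float],
                          target: str = "sbp") -> tuple[float, float]:
    """Mean and SD of reference BP given feature values under the model.

    Gaussian conjugacy: the SBP deviation ``u`` has prior ``N(0, pop_sd^2)``
    and each linked feature contributes an independent Gaussian likelihood
    ``x_j ~ N(a_j + b_j u, tau_j^2)``. Exact for
    :meth:`CohortConfig.homoscedastic` configs, where the pooled BP is a
    single Gaussian; otherwise a moment-matched approximation (the pooled
    SD equals the configured population SD by construction either way).
    Features absent from the mapping, and channels with zero slope, carry
    no information and drop out; ``beat_length`` is conditionally
    independent of BP given ``heart_rate`` and is likewise ignored.
    """
    sigma_u2 = config.sbp_pop_sd**2
    precision = 1.0 / sigma_u2
    weighted = 0.0
    for name, ch in config.feature_link.items():
        if ch.slope == 0.0 or name not in features:
            continue
        precision += ch.slope**2 / ch.noise_sd**2
        weighted += ch.slope * (float(features[name]) - ch.intercept) / ch.noise_sd**2
    v_u = 1.0 / precision
    m_u = v_u * weighted
    if target.lower() == "sbp":
        return config.sbp_pop_mean + m_u, math.sqrt(v_u)
    if target.lower() == "dbp":
        s = config.dbp_pop_sd / config.sbp_pop_sd
        r = config.sbp_dbp_corr
        mean = config.dbp_pop_mean + s * r * m_u
        var = s * s * (r * r * v_u + (1 - r * r) * sigma_u2)
        return mean, math.sqrt(var)
    raise ValueError(f"unknown target {target!r}")


def true_conditional_quantile(config: CohortConfig, features: Mapping[str, float],
                              gamma: float, target: str = "sbp") -> float:
    """Analytic gamma-quantile of reference BP given the feature values.

    The oracle for quantile-recovery tests: under the linear-Gaussian
    generative model the conditional law of BP given the features is
    Gaussian, so the quantile is ``posterior_mean + z_gamma *
    posterior_sd``. At ``gamma=0.5`` this is the conditional mean; the
    0.95-0.50 quantile gap equals ``1.6449 * posterior_sd`` for every
    feature vector (homoscedastic posterior).
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    mean, sd = conditional_posterior(config, features, target=target)
    return mean + float(stats.norm.ppf(gamma)) * sd


def write_config(config: CohortConfig, path) -> None:
    """Serialise a cohort config to YAML (feature links as nested maps)."""
    import yaml

    data = dataclasses.asdict(config)
    data["feature_link"] = {
        k: dataclasses.asdict(v) for k, v in config.feature_link.items()
    }
    data["day_window"] = list(config.day_window)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_config(path) -> CohortConfig:
    """Load a cohort config written by :func:`write_config`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "feature_link" in data:
        data["feature_link"] = {
            k: FeatureChannel(**v) for k, v in data["feature_link"].items()
        }
    if "day_window" in data:
        data["day_window"] = tuple(data["day_window"])
    return CohortConfig(**data)
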