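"""Synthetic ICU cohort generator with class-conditional trend structure.

Real critical-care data (for example MIMIC-III) is access-restricted, so
every stage of the pipeline is exercised on generated cohorts that emulate
its relevant statistical features: 48-hour multichannel stays sampled
irregularly (about one observation per hour per channel), whole windows
knocked out at random, roughly 57% positive prevalence, and creatinine
trajectories engineered so the AKIN labeler reproduces each patient's
intended class exactly.

Noise is an Ornstein-Uhlenbeck physiological drift plus white measurement
noise (clinical series are autocorrelated); monitored channels are sampled
about hourly and labs a few times a day.

The class signal is *trend-borne by construction*.  Positive-class patients
receive, on a configurable subset of channels:

* ``heart_rate`` — a window-aligned zig-zag with (approximately) zero
  window means, faded out near the horizon: visible only to local,
  within-window slopes;
* ``blood_urea_nitrogen`` — a broad triangular excursion with a per-patient
  peak time that returns to baseline before hour 48: visible to both local
  and global trend detection, invisible to the last recorded value;
* ``bicarbonate`` and ``temperature`` — low-amplitude tents spanning the
  whole horizon with a jittered apex, drawn as closely spaced sample pairs
  so within-window slopes are pure noise: only whole-series (global) shape
  fitting aggregates them.

Negative-class patients draw flat trajectories with the same noise.  This
layered design gives the evaluation harness a cohort where combined,
local-only, global-only and last-value representations are separable by
construction, in that order.  ``effect_size`` scales all amplitudes; at 0
the classes are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CHANNELS, ChannelSeries, Cohort, PatientRecord

#: Per-channel (baseline level, noise standard deviation) in native units.
CHANNEL_LEVELS: dict[str, tuple[float, float]] = {
    "heart_rate": (85.0, 8.0),
    "temperature": (37.0, 0.4),
    "systolic_blood_pressure": (120.0, 12.0),
    "diastolic_blood_pressure": (70.0, 8.0),
    "white_blood_cells": (9.0, 2.5),
    "hemoglobin": (11.0, 1.2),
    "platelets": (250.0, 50.0),
    "sodium": (139.0, 3.0),
    "anion_gap": (12.0, 2.0),
    "blood_urea_nitrogen": (22.0, 6.0),
    "potassium": (4.1, 0.4),
    "prothrombin": (14.0, 1.5),
    "calcium": (8.8, 0.5),
    "magnesium": (2.0, 0.2),
    "chloride": (103.0, 3.0),
    "bicarbonate": (24.0, 2.5),
    "phosphate": (3.5, 0.6),
}

#: Channels charted continuously (about hourly): monitored vitals plus
#: blood-gas bicarbonate; the remaining labs are drawn a few times a day.
FREQUENT_CHANNELS = (
    "heart_rate",
    "temperature",
    "systolic_blood_pressure",
    "diastolic_blood_pressure",
    "bicarbonate",
)

#: Signal amplitudes at effect_size = 1, in each channel's native units.
SIGNAL_AMPLITUDES = {
    "blood_urea_nitrogen": 6.0,  # broad triangular excursion, jittered peak
    "heart_rate": 4.0,  # within-window zig-zag (local only)
    "bicarbonate": 2.6,  # low-amplitude full-span tent, jittered apex
    "temperature": 0.42,  # low-amplitude full-span tent, jittered apex
}

#: Channels whose class signal is a full-span tent (slow drift up and back).
TENT_CHANNELS = ("bicarbonate", "temperature")

#: Half-width (hours) of the blood-urea-nitrogen excursion.
SIGNAL_HALF_WIDTHS = {
    "blood_urea_nitrogen": 16.0,
}


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_patients: int = 2000
    prevalence: float = 0.57
    channels: tuple[str, ...] = CHANNELS
    samples_per_hour: float = 1.0
    lab_samples_per_hour: float = 1.0 / 6.0
    missing_window_prob: float = 0.1
    horizon: float = 48.0
    window_hours: float = 2.0
    noise_scale: float = 1.0
    drift_fraction: float = 0.75
    drift_timescale: float = 12.0
    effect_size: float = 1.0
    signal_channels: tuple[str, ...] = (
        "blood_urea_nitrogen",
        "heart_rate",
        "bicarbonate",
        "temperature",
    )
    creatinine_base_range: tuple[float, float] = (0.7, 1.3)
    stay_end: float = 96.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise SyntheticError("prevalence must be in (0, 1)")
        if self.samples_per_hour <= 0 or self.lab_samples_per_hour <= 0:
            raise SyntheticError("sampling rates must be positive")
        if self.n_patients < 1:
            raise SyntheticError("n_patients must be >= 1")
        if not 0 <= self.missing_window_prob < 1:
            raise SyntheticError("missing_window_prob must be in [0, 1)")
        unknown = set(self.signal_channels) - set(self.channels)
        if unknown:
            raise SyntheticError(f"signal channels not in channel set: {sorted(unknown)}")


def _sample_times(rng: np.random.Generator, horizon: float, rate: float) -> np.ndarray:
    """Stratified-jittered times: one sample per 1/rate-hour stratum."""
    n = max(1, int(round(rate * horizon)))
    return np.minimum((np.arange(n) + rng.uniform(0.0, 1.0, n)) / rate, horizon)


def _noise(rng: np.random.Generator, t: np.ndarray, sd: float, cfg: SyntheticConfig) -> np.ndarray:
    """Autocorrelated physiological drift (an Ornstein-Uhlenbeck process)
    plus white measurement noise, with total stationary variance ``sd**2``."""
    sd = sd * cfg.noise_scale
    frac = min(max(cfg.drift_fraction, 0.0), 1.0)
    sd_drift = sd * np.sqrt(frac)
    sd_meas = sd * np.sqrt(1.0 - frac)
    drift = np.zeros(t.size)
    if sd_drift > 0 and t.size:
        tau = max(cfg.drift_timescale, 1e-6)
        x = rng.normal(0.0, sd_drift)
        drift[0] = x
        for k in range(1, t.size):
            rho = np.exp(-(t[k] - t[k - 1]) / tau)
            x = x * rho + rng.normal(0.0, sd_drift * np.sqrt(1.0 - rho * rho))
            drift[k] = x
    return drift + rng.normal(0.0, sd_meas, t.size)


def _signal(
    channel: str,
    t: np.ndarray,
    positive: bool,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    if not positive or channel not in cfg.signal_channels:
        return np.zeros_like(t)
    amp = cfg.effect_size * SIGNAL_AMPLITUDES.get(channel, 0.0)
    if channel == "heart_rate":
        # zig-zag aligned to the window grid: alternating within-window slopes
        # with (approximately) zero window means; faded out over the last
        # hours so the value at the prediction point carries no class signal
        w = cfg.window_hours
        widx = np.minimum(np.floor(t / w).astype(int), int(cfg.horizon / w) - 1)
        sign = np.where(widx % 2 == 0, 1.0, -1.0)
        frac = (t - widx * w) / w  # position within the window, [0, 1)
        fade = np.clip((cfg.horizon - t) / (4.0 * w), 0.0, 1.0)
        return amp * sign * (2.0 * frac - 1.0) * fade
    if channel in TENT_CHANNELS:
        # full-span asymmetric tent with a jittered apex, small against the
        # per-window noise: no single window mean is reliably informative,
        # but the whole-series triangular fit aggregates all windows like a
        # matched filter -- the regime where global trends carry unique value.
        # Zero at both edges, so the last recorded value stays clean.
        c = rng.uniform(cfg.horizon / 4.0, 3.0 * cfg.horizon / 4.0)
        up = t / c
        down = (cfg.horizon - t) / (cfg.horizon - c)
        return amp * np.minimum(up, down)
    # broad triangular excursion with a per-patient peak time: returns to
    # baseline well before the horizon edges (the last recorded value stays
    # uninformative), and the peak misaligns across patients
    half = SIGNAL_HALF_WIDTHS.get(channel, cfg.horizon / 3.0)
    center = rng.uniform(half, cfg.horizon - half)
    return amp * np.maximum(0.0, 1.0 - np.abs(t - center) / half)


def _creatinine(
    rng: np.random.Generator, positive: bool, cfg: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    base = rng.uniform(*cfg.creatinine_base_range)
    t = np.arange(0.0, cfg.stay_end + 1e-9, 12.0)
    jitter = rng.uniform(-0.02, 0.02, t.size)
    v = base + jitter
    if positive:
        # flat inside the horizon, then a 0.05 mg/dL/h climb: the first
        # post-horizon pairwise rise >= 0.3 fixes AKI onset after hour 48
        rise = 0.05 * np.maximum(t - cfg.horizon, 0.0)
        v = v + rise
    return t, np.maximum(v, 0.1)


def generate(config: SyntheticConfig) -> Cohort:
    """Generate a labeled-by-construction cohort (labels left for `label_aki`).

    The positive count is exactly ``round(prevalence * n_patients)``;
    trajectories are engineered so AKIN labeling recovers the intended class
    for every record and no record is excluded by the horizon filters.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.prevalence * config.n_patients))
    intended = np.zeros(config.n_patients, dtype=bool)
    intended[:n_pos] = True
    rng.shuffle(intended)

    m = int(round(config.horizon / config.window_hours))
    pad = len(str(config.n_patients))
    records = []
    for i in range(config.n_patients):
        positive = bool(intended[i])
        channels = {}
        for ch in config.channels:
            level, sd = CHANNEL_LEVELS.get(ch, (0.0, 1.0))
            if ch in TENT_CHANNELS:
                # burst sampling: one closely spaced pair of draws per window
                # (panel-style collection), so within-window slopes are pure
                # measurement noise while window means stay well estimated
                w = config.window_hours
                base = np.arange(m) * w + rng.uniform(0.05, w - 0.2, m)
                t = np.sort(np.concatenate([base, base + 0.1]))
            else:
                rate = (
                    config.samples_per_hour
                    if ch in FREQUENT_CHANNELS
                    else config.lab_samples_per_hour
                )
                t = _sample_times(rng, config.horizon, rate)
            v = level + _signal(ch, t, positive, config, rng) + _noise(rng, t, sd, config)
            # knock out whole windows, but keep at least one sample
            if config.missing_window_prob > 0:
                drop = rng.random(m) < config.missing_window_prob
                widx = np.minimum(
                    np.floor(t / config.window_hours).astype(int), m - 1
                )
                keep = ~drop[widx]
                if keep.any():
                    t, v = t[keep], v[keep]
            channels[ch] = ChannelSeries(ch, t, v)
        ct, cv = _creatinine(rng, positive, config)
        records.append(
            PatientRecord(
                patient_id=f"synth-{i:0{pad}d}",
                channels=channels,
                creatinine=ChannelSeries("creatinine", ct, cv),
                admission_creatinine=float(cv[0]),
                stay_end=config.stay_end,
                died_before_horizon=False,
            )
        )
    return Cohort(records, horizon=config.horizon)


# ---------------------------------------------------------------------------
# Hand-written micro-cohort
# ---------------------------------------------------------------------------

#: Hand-computed AKI labels for the fixture (patient_id -> expected label).
FIXTURE_LABELS: dict[str, int] = {
    "fx-01": 1,  # 1.0 -> 1.4 between hours 50 and 74: delta rise 0.4 >= 0.3
    "fx-02": 1,  # 2.0 -> 3.2 at 72 h: 1.6x baseline within 7 days
    "fx-03": 0,  # 1.0 -> 1.2: neither criterion
    "fx-04": 0,  # constant creatinine
    "fx-05": 1,  # late delta rise at 60 h (retained: onset past horizon)
    "fx-06": 1,  # AKI onset 24 h -> excluded by the horizon filter
    "fx-07": 0,  # admission creatinine 4.5 -> excluded as ESRD
    "fx-08": 0,  # died before horizon -> excluded
    "fx-09": 0,  # slow drift, never qualifying
    "fx-10": 1,  # ratio criterion exactly at 1.5x
    "fx-11": 0,  # empty-window channels, flat creatinine
    "fx-12": 1,  # triangular pulse channel, late delta rise
}

#: Patients of the fixture removed by `apply_exclusions`, with reasons.
FIXTURE_EXCLUDED: dict[str, str] = {
    "fx-06": "aki_within_horizon",
    "fx-07": "esrd",
    "fx-08": "died_within_horizon",
}


def fixture_small() -> Cohort:
    """Deterministic 12-patient, 3-channel micro-cohort for hand checks.

    Covers single-sample windows, empty windows, exact lines, a triangular
    pulse, AKIN-positive and -negative creatinine, and one patient per
    exclusion rule.  Expected labels are in :data:`FIXTURE_LABELS`.
    """

    def series(ch, pts):
        t, v = zip(*pts)
        return ChannelSeries(ch, np.array(t, float), np.array(v, float))

    def rec(pid, hr, bun, bic, creat, died=False):
        channels = {
            "heart_rate": series("heart_rate", hr),
            "blood_urea_nitrogen": series("blood_urea_nitrogen", bun),
            "bicarbonate": series("bicarbonate", bic),
        }
        cr = series("creatinine", creat)
        return PatientRecord(
            patient_id=pid,
            channels=channels,
            creatinine=cr,
            admission_creatinine=float(cr.values[0]),
            stay_end=float(cr.times[-1]),
            died_before_horizon=died,
        )

    line = [(t, 60.0 + 2.0 * t) for t in (0.0, 6.0, 12.0, 24.0, 36.0, 47.0)]  # exact line
    flat = [(t, 24.0) for t in (0.0, 12.0, 24.0, 36.0, 47.0)]
    sparse = [(1.0, 80.0), (30.0, 90.0)]  # mostly empty windows
    tri = [(t, max(30.0 - 1.0 * abs(t - 24.0), 10.0)) for t in np.arange(0.0, 48.1, 4.0)]

    return Cohort(
        [
            rec("fx-01", line, tri, flat, [(0.0, 1.0), (50.0, 1.0), (74.0, 1.4)]),
            rec("fx-02", sparse, flat, flat, [(0.0, 2.0), (72.0, 3.2)]),
            rec("fx-03", line, flat, flat, [(0.0, 1.0), (100.0, 1.2)]),
            rec("fx-04", [(5.0, 72.0)], flat, flat, [(0.0, 0.9), (48.0, 0.9), (90.0, 0.9)]),
            rec("fx-05", line, tri, sparse, [(0.0, 1.0), (40.0, 1.1), (60.0, 1.45)]),
            rec("fx-06", flat, flat, flat, [(0.0, 1.0), (24.0, 1.5)]),
            rec("fx-07", line, flat, flat, [(0.0, 4.5), (60.0, 4.6)]),
            rec("fx-08", [(0.0, 100.0), (10.0, 40.0)], flat, flat, [(0.0, 1.0)], died=True),
            rec("fx-09", flat, sparse, flat, [(0.0, 1.0), (50.0, 1.1), (120.0, 1.25)]),
            rec("fx-10", tri, line, flat, [(0.0, 1.0), (30.0, 0.8), (100.0, 1.2)]),
            rec("fx-11", sparse, sparse, sparse, [(0.0, 1.1), (96.0, 1.15)]),
            rec("fx-12", tri, tri, flat, [(0.0, 1.2), (47.0, 1.3), (52.0, 1.6)]),
        ],
        horizon=48.0,
    )


__all__ = [
    "CHANNEL_LEVELS",
    "SIGNAL_AMPLITUDES",
    "SyntheticConfig",
    "SyntheticError",
    "generate",
    "fixture_small",
    "FIXTURE_LABELS",
    "FIXTURE_EXCLUDED",
]
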