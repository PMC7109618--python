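"""Cohort domain model: patient records, long-format I/O, AKIN labeling, exclusions.

A cohort is a set of ICU stays observed over a fixed prediction horizon
(default 48 h from admission).  Each stay carries irregularly sampled series
for up to 17 input channels (vital signs and laboratory tests) plus a serum
creatinine series covering the whole stay, which is used *only* to derive the
acute-kidney-injury (AKI) outcome label via the AKIN creatinine criteria:

* an increase of >= 0.3 mg/dL between two measurements no more than 48 h
  apart, or
* a measurement >= 1.5x the baseline (lowest creatinine observed so far
  during the stay) within 7 days of the time that baseline was attained.

The on-disk exchange format is a long-format CSV with columns
``patient_id,channel,time_hours,value``.  Death before the horizon is
encoded with the sentinel channel ``died_flag`` so the format stays
four-column and round-trips losslessly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 17 input channels (4 vital signs, 3 hematology, 10 biochemistry).
CHANNELS: tuple[str, ...] = (
    "heart_rate",
    "temperature",
    "systolic_blood_pressure",
    "diastolic_blood_pressure",
    "white_blood_cells",
    "hemoglobin",
    "platelets",
    "sodium",
    "anion_gap",
    "blood_urea_nitrogen",
    "potassium",
    "prothrombin",
    "calcium",
    "magnesium",
    "chloride",
    "bicarbonate",
    "phosphate",
)

CREATININE = "creatinine"
DIED_FLAG = "died_flag"

#: Default horizon (hours of data used for prediction).
DEFAULT_HORIZON = 48.0


class CohortError(ValueError):
    """Malformed cohort input."""


class LabelingError(CohortError):
    """AKI labeling impossible (e.g. no creatinine measurements)."""


@dataclass(frozen=True)
class Sample:
    """A single timestamped observation (time in hours since ICU admission)."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise CohortError(f"negative sample time {self.time}")
        if not np.isfinite(self.value):
            raise CohortError(f"non-finite sample value {self.value}")


@dataclass
class ChannelSeries:
    """One channel's samples for one patient, sorted by nondecreasing time."""

    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise CohortError("times and values must be 1-D arrays of equal length")
        if t.size and t.min() < 0:
            raise CohortError(f"negative time in channel {self.channel!r}")
        if not np.all(np.isfinite(v)):
            raise CohortError(f"non-finite value in channel {self.channel!r}")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]

    def __len__(self) -> int:
        return int(self.times.size)

    def truncated(self, horizon: float) -> "ChannelSeries":
        keep = self.times <= horizon
        return ChannelSeries(self.channel, self.times[keep], self.values[keep])

    def last_value(self) -> float:
        if not len(self):
            raise CohortError(f"channel {self.channel!r} is empty")
        return float(self.values[-1])

    def samples(self) -> list[Sample]:
        return [Sample(float(t), float(v)) for t, v in zip(self.times, self.values)]


@dataclass
class AKILabel:
    """Outcome of AKIN labeling: binary label, onset time, firing criterion."""

    label: int
    onset: float | None = None
    reason: str | None = None  # "delta", "ratio" or "both"


@dataclass
class PatientRecord:
    """One ICU stay: input channels over the horizon plus the creatinine series."""

    patient_id: str
    channels: dict[str, ChannelSeries] = field(default_factory=dict)
    creatinine: ChannelSeries | None = None
    admission_creatinine: float | None = None
    stay_end: float = 0.0
    died_before_horizon: bool = False
    label: int | None = None
    aki_onset: float | None = None
    aki_reason: str | None = None


@dataclass
class Cohort:
    """A sequence of patient records sharing one prediction horizon."""

    records: list[PatientRecord]
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> np.ndarray:
        out = []
        for r in self.records:
            if r.label is None:
                raise CohortError(f"patient {r.patient_id} is unlabeled")
            out.append(r.label)
        return np.asarray(out, dtype=int)

    def prevalence(self) -> float:
        y = self.labels()
        return float(y.mean())

    def summary(self) -> dict:
        labeled = [r for r in self.records if r.label is not None]
        out = {"n_patients": len(self.records), "horizon_hours": self.horizon}
        if labeled and len(labeled) == len(self.records):
            y = self.labels()
            out["n_positive"] = int(y.sum())
            out["n_negative"] = int((1 - y).sum())
            out["prevalence"] = float(y.mean())
        return out


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

_KNOWN_CHANNELS = set(CHANNELS) | {CREATININE, DIED_FLAG}
_REQUIRED_COLUMNS = ["patient_id", "channel", "time_hours", "value"]


def read_long_csv(
    path,
    horizon: float = DEFAULT_HORIZON,
    on_unknown_channel: str = "warn",
) -> Cohort:
    """Read a long-format observation CSV into a :class:`Cohort`.

    Input channels are truncated at the horizon; creatinine keeps the whole
    stay.  ``on_unknown_channel`` is ``"warn"`` (keep, with a warning) or
    ``"raise"``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "channel": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing required columns: {missing}")
    if not len(df):
        return Cohort([], horizon=horizon)

    for col in ("time_hours", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise CohortError(f"malformed {col!r} at line {int(bad[0]) + 2}")
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise CohortError(f"missing {col!r} at line {line}")
        df[col] = coerced.astype(float)

    neg = df.index[df["time_hours"] < 0]
    if len(neg):
        raise CohortError(f"negative time_hours at line {int(neg[0]) + 2}")

    unknown = sorted(set(df["channel"]) - _KNOWN_CHANNELS)
    if unknown:
        if on_unknown_channel == "raise":
            raise CohortError(f"unknown channels: {unknown}")
        warnings.warn(f"unknown channels kept as-is: {unknown}", stacklevel=2)

    records = []
    for pid, grp in df.groupby("patient_id", sort=True):
        channels: dict[str, ChannelSeries] = {}
        creatinine = None
        died = False
        stay_end = 0.0
        for ch, sub in grp.groupby("channel", sort=True):
            series = ChannelSeries(ch, sub["time_hours"].to_numpy(), sub["value"].to_numpy())
            stay_end = max(stay_end, float(series.times[-1]) if len(series) else 0.0)
            if ch == DIED_FLAG:
                died = bool(np.any(series.values > 0))
            elif ch == CREATININE:
                creatinine = series
            else:
                channels[ch] = series.truncated(horizon)
        adm = float(creatinine.values[0]) if creatinine is not None and len(creatinine) else None
        records.append(
            PatientRecord(
                patient_id=str(pid),
                channels=channels,
                creatinine=creatinine,
                admission_creatinine=adm,
                stay_end=stay_end,
                died_before_horizon=died,
            )
        )
    return Cohort(records, horizon=horizon)


def write_long_csv(cohort: Cohort, path) -> None:
    """Write a cohort back to long format (inverse of :func:`read_long_csv`)."""
    rows: list[tuple[str, str, float, float]] = []
    for rec in cohort:
        for ch in sorted(rec.channels):
            s = rec.channels[ch]
            rows.extend((rec.patient_id, ch, float(t), float(v)) for t, v in zip(s.times, s.values))
        if rec.creatinine is not None:
            s = rec.creatinine
            rows.extend(
                (rec.patient_id, CREATININE, float(t), float(v))
                for t, v in zip(s.times, s.values)
            )
        if rec.died_before_horizon:
            rows.append((rec.patient_id, DIED_FLAG, 0.0, 1.0))
    df = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AKIN labeling
# ---------------------------------------------------------------------------


def label_aki(
    record: PatientRecord,
    *,
    delta: float = 0.3,
    delta_window: float = 48.0,
    ratio: float = 1.5,
    ratio_window: float = 168.0,
    pairing: str = "pairwise",
) -> AKILabel:
    """Apply the AKIN creatinine criteria to one record.

    ``pairing`` selects whether the 0.3 mg/dL rise is checked over every
    sample pair within 48 h (``"pairwise"``, the default) or only adjacent
    samples (``"consecutive"``).  The 1.5x criterion uses the running minimum
    as baseline and requires the flagged sample within ``ratio_window`` hours
    of the time that minimum was first attained.
    """
    if record.creatinine is None or len(record.creatinine) == 0:
        raise LabelingError(f"patient {record.patient_id}: no creatinine measurements")
    t = record.creatinine.times
    v = record.creatinine.values
    n = t.size

    # decimal clinical thresholds are not exactly representable in binary;
    # the tiny tolerance keeps exact-at-threshold measurements flagged
    eps = 1e-9
    delta_hit = np.zeros(n, dtype=bool)
    if pairing == "pairwise":
        for j in range(1, n):
            lo = np.searchsorted(t, t[j] - delta_window, side="left")
            if lo < j:
                delta_hit[j] = (v[j] - v[lo:j].min()) >= delta - eps
    elif pairing == "consecutive":
        for j in range(1, n):
            if t[j] - t[j - 1] <= delta_window:
                delta_hit[j] = (v[j] - v[j - 1]) >= delta - eps
    else:  # pragma: no cover - config validation
        raise CohortError(f"unknown pairing {pairing!r}")

    runmin = np.minimum.accumulate(v)
    attain = np.empty(n)
    cur_t = t[0]
    for j in range(n):
        if j and runmin[j] < runmin[j - 1]:
            cur_t = t[j]
        attain[j] = cur_t
    # runmin includes the sample itself, so a sample can never flag against
    # its own value (ratio > 1); runmin > 0 guards pathological zero baselines
    ratio_hit = (v >= ratio * runmin - eps) & (runmin > 0) & ((t - attain) <= ratio_window)

    hit = delta_hit | ratio_hit
    if not hit.any():
        return AKILabel(0)
    j = int(np.argmax(hit))
    if delta_hit[j] and ratio_hit[j]:
        reason = "both"
    elif delta_hit[j]:
        reason = "delta"
    else:
        reason = "ratio"
    return AKILabel(1, onset=float(t[j]), reason=reason)


def label_cohort(cohort: Cohort, **kwargs) -> Cohort:
    """Label every record in place (returns the same cohort for chaining)."""
    for rec in cohort:
        res = label_aki(rec, **kwargs)
        rec.label = res.label
        rec.aki_onset = res.onset
        rec.aki_reason = res.reason
    return cohort


# ---------------------------------------------------------------------------
# Cohort exclusions
# ---------------------------------------------------------------------------

REASON_DIED = "died_within_horizon"
REASON_AKI = "aki_within_horizon"
REASON_ESRD = "esrd"


def apply_exclusions(
    cohort: Cohort,
    *,
    esrd_creatinine: float = 4.0,
    label_kwargs: dict | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Drop stays that died or developed AKI within the horizon, or look like
    end-stage renal disease on admission (creatinine > 4 mg/dL).

    Returns the filtered cohort and a log with one ``(patient_id, reason)``
    row per excluded stay (first matching rule wins).  Idempotent.
    """
    kept: list[PatientRecord] = []
    log: list[tuple[str, str]] = []
    for rec in cohort:
        if rec.label is None:
            res = label_aki(rec, **(label_kwargs or {}))
            rec.label = res.label
            rec.aki_onset = res.onset
            rec.aki_reason = res.reason
        if rec.died_before_horizon:
            log.append((rec.patient_id, REASON_DIED))
        elif rec.label == 1 and rec.aki_onset is not None and rec.aki_onset <= cohort.horizon:
            log.append((rec.patient_id, REASON_AKI))
        elif rec.admission_creatinine is not None and rec.admission_creatinine > esrd_creatinine:
            log.append((rec.patient_id, REASON_ESRD))
        else:
            kept.append(rec)
    return Cohort(kept, horizon=cohort.horizon), pd.DataFrame(log, columns=["patient_id", "reason"])


def write_summary_json(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.summary(), fh, indent=2)


__all__ = [
    "CHANNELS",
    "CREATININE",
    "DIED_FLAG",
    "DEFAULT_HORIZON",
    "Sample",
    "ChannelSeries",
    "PatientRecord",
    "Cohort",
    "AKILabel",
    "CohortError",
    "LabelingError",
    "read_long_csv",
    "write_long_csv",
    "label_aki",
    "label_cohort",
    "apply_exclusions",
    "write_summary_json",
]
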