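"""Per-patient trend feature extraction as a scikit-learn transformer.

Four feature representations of a 48 h multichannel ICU stay are supported:

``last_value``
    One number per channel: the last recorded value before the prediction
    point (the most common representation in the adverse-event literature).
``local``
    The horizon is segmented into ``m`` windows; each window of each channel
    is fitted with the best structure detector, contributing
    ``(a, b, c, index)`` — so ``4*m`` features per channel.
``global``
    The structure detectors are fitted once per channel to the series of
    per-window means (PAA), contributing ``(G_a, G_b, G_c, G_index)``.
``combined``
    Local features followed by global features, per channel:
    ``4*m + 4`` features per channel (1700 columns at 17 channels, m=24).

Missing data never changes the feature-vector length: empty windows are
imputed at the window-mean level (yielding constant fits), and a channel
with no samples at all falls back to an all-constant fit at the cohort
median learned during :meth:`TrendFeaturizer.fit`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CHANNELS, Cohort, PatientRecord
from .structures import DetectorConfig, FitSeries, StructureFit, best_fit
from .windowing import WindowGrid, paa, segment

MODES = ("last_value", "local", "global", "combined")


def _records(X) -> list[PatientRecord]:
    if isinstance(X, Cohort):
        return list(X.records)
    return list(X)


def _collapse_duplicate_times(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if uniq.size == t.size:
        return t, v
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, v)
    return uniq, sums / counts


class TrendFeaturizer(BaseEstimator, TransformerMixin):
    """Extract last-value, local-trend, global-trend or combined features.

    Parameters
    ----------
    mode : {"last_value", "local", "global", "combined"}
    window_hours : float
        Window width; ``horizon / window_hours`` must be an integer.
    horizon : float
        Prediction point, hours from admission.
    channels : sequence of str or None
        Channel set and order; defaults to the standard 17 input channels.
    imputation : {"carry", "linear"}
        Empty-window policy for the PAA step.
    one_hot_index : bool
        Emit the winning family index as five indicator columns instead of
        the ordinal 1-5 value.
    max_iter, tol, n_starts, polish_top, detector_seed :
        Numerical settings for the simplex-searched structure fits.

    Attributes
    ----------
    channels_ : list of str
        Channel order used for transform.
    medians_ : dict
        Per-channel training median, the absent-channel fallback level.
    feature_names_ : list of str
        Deterministic column names of the transform output.
    """

    def __init__(
        self,
        mode: str = "combined",
        window_hours: float = 2.0,
        horizon: float = 48.0,
        channels=None,
        imputation: str = "carry",
        one_hot_index: bool = False,
        max_iter: int = 150,
        tol: float = 1e-8,
        n_starts: int = 5,
        polish_top: int = 1,
        detector_seed: int = 0,
    ):
        self.mode = mode
        self.window_hours = window_hours
        self.horizon = horizon
        self.channels = channels
        self.imputation = imputation
        self.one_hot_index = one_hot_index
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts
        self.polish_top = polish_top
        self.detector_seed = detector_seed

    # -- sklearn plumbing ---------------------------------------------------

    def _grid(self) -> WindowGrid:
        return WindowGrid(self.horizon, self.window_hours)

    def _config(self) -> DetectorConfig:
        return DetectorConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            n_starts=self.n_starts,
            polish_top=self.polish_top,
            seed=self.detector_seed,
        )

    def fit(self, X, y=None):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        grid = self._grid()  # validates horizon/width
        records = _records(X)
        self.channels_ = list(self.channels) if self.channels is not None else list(CHANNELS)
        self.medians_ = {}
        for ch in self.channels_:
            vals = [r.channels[ch].values for r in records if ch in r.channels and len(r.channels[ch])]
            self.medians_[ch] = float(np.median(np.concatenate(vals))) if vals else 0.0
        self.feature_names_ = self._build_names(grid.m)
        self.n_features_in_ = len(records)
        return self

    def _build_names(self, m: int) -> list[str]:
        def block(prefix: str) -> list[str]:
            if self.one_hot_index:
                tail = [f"{prefix}__index__{k}" for k in range(1, 6)]
            else:
                tail = [f"{prefix}__index"]
            return [f"{prefix}__a", f"{prefix}__b", f"{prefix}__c"] + tail

        names: list[str] = []
        for ch in self.channels_:
            if self.mode == "last_value":
                names.append(f"{ch}__last_value")
                continue
            if self.mode in ("local", "combined"):
                for i in range(1, m + 1):
                    names.extend(block(f"{ch}__w{i}"))
            if self.mode in ("global", "combined"):
                names.extend(block(f"{ch}__G"))
        return names

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    # -- feature extraction -------------------------------------------------

    def _emit(self, row: list[float], fit: StructureFit) -> None:
        row.extend((fit.a, fit.b, fit.c))
        if self.one_hot_index:
            row.extend(1.0 if k == fit.index else 0.0 for k in range(1, 6))
        else:
            row.append(float(fit.index))

    def _channel_features(self, rec: PatientRecord, ch: str, grid, config) -> list[float]:
        series = rec.channels.get(ch)
        med = self.medians_[ch]
        row: list[float] = []
        absent = series is None or len(series) == 0
        if self.mode == "last_value":
            if absent:
                warnings.warn(
                    f"patient {rec.patient_id}: channel {ch!r} absent; using cohort median",
                    stacklevel=2,
                )
                row.append(med)
            else:
                row.append(series.last_value())
            return row

        if absent:
            warnings.warn(
                f"patient {rec.patient_id}: channel {ch!r} absent; all-constant fallback",
                stacklevel=2,
            )
            fallback = StructureFit(1, med, 0.0, 0.0, 0.0)
            n_blocks = (grid.m if self.mode in ("local", "combined") else 0) + (
                1 if self.mode in ("global", "combined") else 0
            )
            for _ in range(n_blocks):
                self._emit(row, fallback)
            return row

        ws = segment(series.truncated(grid.horizon), grid)
        avg = paa(ws, imputation=self.imputation)
        if self.mode in ("local", "combined"):
            starts = grid.edges[:-1]
            for i in range(grid.m):
                t, v = ws.windows[i]
                if t.size > 1:
                    # duplicate timestamps (repeated draws) collapse to their
                    # mean so the fit input has strictly increasing times
                    t, v = _collapse_duplicate_times(t, v)
                if t.size == 0:
                    # imputed single-value window: constant at the imputed mean
                    fit = StructureFit(1, float(avg.values[i]), 0.0, 0.0, 0.0)
                elif t.size == 1:
                    fit = StructureFit(1, float(v[0]), 0.0, 0.0, 0.0)
                else:
                    fit = best_fit(FitSeries(t - starts[i], v), config)
                self._emit(row, fit)
        if self.mode in ("global", "combined"):
            gfit = best_fit(FitSeries(np.arange(grid.m, dtype=float), avg.values), config)
            self._emit(row, gfit)
        return row

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "channels_"):
            raise ValueError("TrendFeaturizer is not fitted")
        grid = self._grid()
        config = self._config()
        records = _records(X)
        rows = []
        for rec in records:
            row: list[float] = []
            for ch in self.channels_:
                row.extend(self._channel_features(rec, ch, grid, config))
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=self.feature_names_,
            index=[r.patient_id for r in records],
            dtype=float,
        )


def local_features(record: PatientRecord, grid: WindowGrid, **kwargs) -> pd.DataFrame:
    """One-record convenience wrapper: local trend vector for every channel."""
    f = TrendFeaturizer(mode="local", window_hours=grid.width, horizon=grid.horizon, **kwargs)
    return f.fit([record]).transform([record])


def global_features(record: PatientRecord, grid: WindowGrid, **kwargs) -> pd.DataFrame:
    """One-record convenience wrapper: global trend vector for every channel."""
    f = TrendFeaturizer(mode="global", window_hours=grid.width, horizon=grid.horizon, **kwargs)
    return f.fit([record]).transform([record])


def last_value_features(record: PatientRecord, **kwargs) -> pd.DataFrame:
    """One-record convenience wrapper: last recorded value per channel."""
    f = TrendFeaturizer(mode="last_value", **kwargs)
    return f.fit([record]).transform([record])


def assemble(
    cohort: Cohort,
    mode: str,
    grid: WindowGrid | None = None,
    featurizer: TrendFeaturizer | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Build the labeled feature matrix for a whole cohort.

    ``mode`` is one of the :data:`MODES` or ``"symbolic"`` (which delegates
    to :class:`trendsieve.symbolic.TIRPFeaturizer`).  The label column is
    named ``"aki"``.
    """
    y = cohort.labels()  # raises if any record is unlabeled
    if mode == "symbolic":
        from .symbolic import TIRPFeaturizer

        grid = grid or WindowGrid()
        feat = featurizer or TIRPFeaturizer(
            window_hours=grid.width, horizon=grid.horizon, **kwargs
        )
    else:
        grid = grid or WindowGrid()
        feat = featurizer or TrendFeaturizer(
            mode=mode, window_hours=grid.width, horizon=grid.horizon, **kwargs
        )
    X = feat.fit(cohort.records).transform(cohort.records)
    X["aki"] = y
    return X


__all__ = [
    "MODES",
    "TrendFeaturizer",
    "local_features",
    "global_features",
    "last_value_features",
    "assemble",
]
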