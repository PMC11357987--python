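"""Core containers shared by all model families.

A :class:`Recording` is the channels x time matrix every predictor consumes;
a :class:`PredictionSet` holds one-step-ahead predictions ``yhat(t|t-1)`` and
their residuals aligned to test-time indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass
class Recording:
    """A multichannel time series.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_samples)``; all entries finite.
    sampling_interval
        Seconds per sample (e.g. 0.72 for TR-resolution fMRI, 0.002 for
        500 Hz iEEG).
    labels
        Optional channel names; defaults to ``ch0, ch1, ...``.
    """

    values: np.ndarray
    sampling_interval: float = 1.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise InvalidParameterError("values must be a 2-D channels x time array")
        if self.values.shape[1] < 2:
            raise InvalidParameterError("a Recording needs at least 2 time samples")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("Recording values must be finite")
        if not self.sampling_interval > 0:
            raise InvalidParameterError("sampling_interval must be positive")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(self.values.shape[0])]
        elif len(self.labels) != self.values.shape[0]:
            raise InvalidParameterError("labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples * self.sampling_interval

    def slice_time(self, start: int, stop: int) -> "Recording":
        """A new Recording over the half-open sample range ``[start, stop)``."""
        return Recording(self.values[:, start:stop].copy(),
                         self.sampling_interval, list(self.labels))


@dataclass
class PredictionSet:
    """One-step-ahead predictions aligned to test-time indices.

    ``indices[k]`` is the 0-based time index ``t`` of the test segment at
    which ``predictions[:, k]`` estimates ``y(t)`` from data strictly before
    ``t``. Residuals satisfy ``residuals = actual - predictions`` elementwise.
    """

    predictions: np.ndarray
    residuals: np.ndarray
    indices: np.ndarray
    fit_time: float = 0.0
    predict_time: float = 0.0
    burn_in: int = 0  # leading predictions to exclude from scoring

    def __post_init__(self) -> None:
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=float))
        self.residuals = np.atleast_2d(np.asarray(self.residuals, dtype=float))
        self.indices = np.asarray(self.indices, dtype=int)
        if self.predictions.shape != self.residuals.shape:
            raise InvalidParameterError("predictions and residuals shapes differ")
        if self.predictions.shape[1] != self.indices.size:
            raise InvalidParameterError("index list length must match predictions")

    @classmethod
    def from_actual(cls, actual: np.ndarray, predictions: np.ndarray,
                    indices: np.ndarray, **kw) -> "PredictionSet":
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
        return cls(predictions, actual - predictions, np.asarray(indices), **kw)

    @property
    def scored(self) -> "PredictionSet":
        """The prediction set with burn-in predictions dropped."""
        if self.burn_in == 0:
            return self
        b = self.burn_in
        return PredictionSet(self.predictions[:, b:], self.residuals[:, b:],
                             self.indices[b:], self.fit_time, self.predict_time, 0)

    def actual(self) -> np.ndarray:
        return self.predictions + self.residuals
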