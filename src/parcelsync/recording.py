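"""In-memory containers for parcel-level time series.

A :class:`ParcelRecording` holds real-valued trial data (trials x parcels x
samples) with its sampling rate, parcel labels, and the time of the first
sample relative to the task event (target onset).  Its complex counterpart
:class:`AnalyticRecording` is produced by the Hilbert transform of a
band-limited recording and additionally remembers the frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, LabelError


def _validate_common(data: np.ndarray, rate: float, labels: tuple[str, ...]) -> None:
    if data.ndim != 3:
        raise DegenerateInputError(
            f"data must be trials x parcels x samples, got ndim={data.ndim}"
        )
    if data.shape[0] < 1 or data.shape[2] < 1:
        raise DegenerateInputError(f"empty recording: shape={data.shape}")
    if rate <= 0:
        raise DegenerateInputError(f"sampling rate must be positive, got {rate}")
    if len(labels) != data.shape[1]:
        raise LabelError(
            f"{len(labels)} labels for {data.shape[1]} parcels"
        )
    if len(set(labels)) != len(labels):
        raise LabelError("duplicate parcel labels")


@dataclass(frozen=True)
class ParcelRecording:
    """Real-valued parcel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_parcels, n_samples)``.
    rate
        Sampling rate in Hz.
    labels
        One label per parcel.
    t0
        Time of the first sample in seconds, relative to target onset.
    """

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        _validate_common(data, self.rate, self.labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to target onset."""
        return self.t0 + np.arange(self.n_samples) / self.rate

    def parcel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"unknown parcel label: {label!r}") from None

    def with_data(self, data: np.ndarray, t0: float | None = None) -> "ParcelRecording":
        return replace(self, data=data, t0=self.t0 if t0 is None else t0)


@dataclass(frozen=True)
class AnalyticRecording:
    """Complex analytic parcel time series, tagged with its band (Hz)."""

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    band: tuple[float, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        data = np.asarray(self.data, dtype=complex)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "band", (float(self.band[0]), float(self.band[1])))
        _validate_common(data, self.rate, self.labels)
        if not self.band[0] < self.band[1]:
            raise DegenerateInputError(f"band low >= high: {self.band}")

    n_trials = ParcelRecording.n_trials
    n_parcels = ParcelRecording.n_parcels
    n_samples = ParcelRecording.n_samples
    times = ParcelRecording.times
    parcel_index = ParcelRecording.parcel_index

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in radians, same shape as ``data``."""
        return np.angle(self.data)

    @property
    def envelope(self) -> np.ndarray:
        """Instantaneous amplitude, same shape as ``data``."""
        return np.abs(self.data)

    def with_data(self, data: np.ndarray, t0: float | None = None) -> "AnalyticRecording":
        return replace(self, data=data, t0=self.t0 if t0 is None else t0)
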