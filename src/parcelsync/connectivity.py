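"""Phase-locking connectivity estimators (PLV and corrected-imaginary PLV).

For two instantaneous-phase series ``phi_x``, ``phi_y`` over ``N`` samples,
let ``C = mean(exp(1j * (phi_x - phi_y)))`` be the circular mean of the
phase differences.  The classic phase locking value is ``PLV = |C|``: it is
1 under perfect locking at any lag and near 0 for unrelated phases — but it
is also 1 for *zero-lag* locking, which is exactly what instantaneous
volume conduction / source leakage produces.  The corrected imaginary PLV

    ciPLV = |Im(C)| / sqrt(1 - Re(C) ** 2)

keeps only the component of locking that cannot be explained by a zero or
pi phase lag, and is therefore insensitive to instantaneous linear mixing.
When ``|Re(C)| -> 1`` (perfect zero-lag locking) the expression is 0/0 and
is defined as 0: the statistic's purpose is to discard precisely that case.

The all-pairs estimator computes the statistic within each trial over time
samples and then averages across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionError
from .recording import AnalyticRecording

#: |Re C| closer to 1 than this is treated as perfect zero-lag locking.
_ZERO_LAG_TOL = 1e-12

_VALID_METHODS = ("plv", "ciplv")


def _circular_mean(phase_x: np.ndarray, phase_y: np.ndarray) -> complex:
    x = np.asarray(phase_x, dtype=float)
    y = np.asarray(phase_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(
            f"phase series must be 1-D with equal length, got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise DegenerateInputError("need at least 2 phase samples")
    return complex(np.mean(np.exp(1j * (x - y))))


def plv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Classic phase locking value of two phase series (radians)."""
    return abs(_circular_mean(phase_x, phase_y))


def ciplv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Corrected imaginary PLV of two phase series (radians)."""
    c = _circular_mean(phase_x, phase_y)
    re = np.atleast_1d(np.asarray(c.real))
    im = np.atleast_1d(np.asarray(c.imag))
    return float(_ciplv_from_mean(re, im)[0])


def _ciplv_from_mean(re: np.ndarray, im: np.ndarray) -> np.ndarray:
    denom_sq = 1.0 - re**2
    degenerate = denom_sq <= _ZERO_LAG_TOL * 2.0  # |re| within ~1e-12 of 1
    out = np.zeros(np.broadcast(re, im).shape)
    safe = ~degenerate
    out[safe] = np.abs(im[safe]) / np.sqrt(denom_sq[safe])
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric parcels x parcels matrix of phase-locking values.

    ``values[i, j]`` is the trial-averaged statistic between parcels ``i``
    and ``j``; the diagonal is 1 for ``plv`` (a signal is perfectly locked
    to itself) and 0 for ``ciplv`` (self-locking is zero-lag by definition).
    """

    values: np.ndarray
    method: str
    band: tuple[float, float]
    labels: tuple[str, ...]
    n_trials: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.method not in _VALID_METHODS:
            raise DegenerateInputError(f"method must be one of {_VALID_METHODS}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"values must be square, got shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise DimensionError(
                f"{len(self.labels)} labels for a {v.shape[0]}-parcel matrix"
            )

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def lookup(self, label_a: str, label_b: str) -> float:
        i = self.labels.index(label_a)
        j = self.labels.index(label_b)
        return float(self.values[i, j])


def connectivity_matrix(rec: AnalyticRecording, method: str = "ciplv") -> ConnectivityMatrix:
    """All-pairs phase-locking matrix of an analytic recording.

    The statistic is computed over time samples within each trial and then
    averaged arithmetically across trials.

    Parameters
    ----------
    rec
        Analytic (complex) recording; phases are the complex arguments.
    method
        ``"plv"`` or ``"ciplv"``.

    Returns
    -------
    ConnectivityMatrix
        Symmetric, entries in [0, 1], diagonal fixed by the method.
    """
    if method not in _VALID_METHODS:
        raise DegenerateInputError(f"method must be one of {_VALID_METHODS}")
    if rec.n_parcels < 2:
        raise DegenerateInputError("connectivity needs at least 2 parcels")
    if rec.n_samples < 2:
        raise DegenerateInputError("connectivity needs at least 2 samples per trial")

    # unit phasors; exp(i*angle(z)) is robust to amplitude variation
    z = np.exp(1j * np.angle(rec.data))  # (trials, parcels, samples)
    n = rec.n_samples
    # per-trial circular mean matrix C[t] = Z Z^H / n
    c = np.einsum("tps,tqs->tpq", z, z.conj()) / n

    if method == "plv":
        per_trial = np.abs(c)
    else:
        per_trial = _ciplv_from_mean(c.real, c.imag)
    values = per_trial.mean(axis=0)
    # enforce exact symmetry lost to float noise in the einsum
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0 if method == "plv" else 0.0)
    return ConnectivityMatrix(
        values=values,
        method=method,
        band=rec.band,
        labels=rec.labels,
        n_trials=rec.n_trials,
    )
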