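"""Band-pass filtering, analytic signal, and analysis-window selection.

The connectivity estimators downstream operate on instantaneous phase, so
this module implements the canonical narrowband preparation: zero-phase
band-pass filtering (4th-order Butterworth run forward and backward, hence
an effective 8th-order magnitude response with no group delay), the Hilbert
analytic signal, and half-open time-window selection.

The Hilbert transform should be applied to the full trial and the analysis
window cut afterwards: computing the analytic signal on a short window
directly introduces Gibbs ringing at its edges.
"""

from __future__ import annotations

from typing import TypeVar, Union

import numpy as np
from scipy import signal as sps

from .errors import BandError, DegenerateInputError, WindowError
from .recording import AnalyticRecording, ParcelRecording

Rec = TypeVar("Rec", ParcelRecording, AnalyticRecording)

#: Butterworth order of each pass (filtfilt doubles the effective order).
FILTER_ORDER = 4

#: Reflect padding, in multiples of the longest period in the pass-band.
_PAD_CYCLES = 3


def _design(low: float, high: float, rate: float) -> np.ndarray:
    return sps.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=rate, output="sos")


def warmup_samples(low: float, rate: float) -> int:
    """Filter warm-up length: a few cycles of the slowest pass-band component."""
    return int(np.ceil(_PAD_CYCLES * rate / low))


def bandpass_filter(rec: ParcelRecording, low: float, high: float) -> ParcelRecording:
    """Zero-phase band-pass filter of every trial and parcel.

    Parameters
    ----------
    rec
        Input recording.
    low, high
        Band edges in Hz; must satisfy ``0 < low < high < rate / 2``.

    Returns
    -------
    ParcelRecording
        Same shape, labels and time axis; band-limited content.
    """
    nyquist = rec.rate / 2.0
    if not 0.0 < low < high < nyquist:
        raise BandError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist={nyquist} Hz"
        )
    pad = warmup_samples(low, rec.rate)
    if rec.n_samples <= pad:
        raise DegenerateInputError(
            f"{rec.n_samples} samples is shorter than the filter warm-up ({pad})"
        )
    sos = _design(low, high, rec.rate)
    # reflect-pad explicitly, filter with no further padding, trim
    out = sps.sosfiltfilt(sos, rec.data, axis=-1, padtype="even", padlen=pad)
    return rec.with_data(out)


def analytic_signal(rec: ParcelRecording, band: tuple[float, float]) -> AnalyticRecording:
    """Hilbert analytic signal of an (already band-limited) recording.

    The caller guarantees ``rec`` was filtered to ``band``; this function
    only constructs the complex representation whose real part is the input
    and whose argument is the instantaneous phase.
    """
    if rec.n_samples < 2:
        raise DegenerateInputError("analytic signal needs at least 2 samples")
    z = sps.hilbert(rec.data, axis=-1)
    return AnalyticRecording(
        data=z, rate=rec.rate, labels=rec.labels, band=band, t0=rec.t0
    )


def select_window(rec: Rec, start: float, end: float) -> Rec:
    """Cut the half-open time window ``[start, end)`` (seconds re target onset).

    A sample at time ``t`` is kept iff ``start <= t < end``.  ``t0`` of the
    result is the time of the first retained sample.
    """
    if not start < end:
        raise WindowError(f"window start {start} must precede end {end}")
    # work in sample indices; the 1e-6-sample slack absorbs float round-off
    # of the time axis without breaking the half-open convention
    first = int(np.ceil((start - rec.t0) * rec.rate - 1e-6))
    stop = int(np.ceil((end - rec.t0) * rec.rate - 1e-6))
    first = max(first, 0)
    stop = min(stop, rec.n_samples)
    if first >= stop:
        t = rec.times
        raise WindowError(
            f"window [{start}, {end}) does not intersect recording "
            f"[{t[0]}, {t[-1] + 1 / rec.rate})"
        )
    return rec.with_data(
        rec.data[:, :, first:stop], t0=rec.t0 + first / rec.rate
    )
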