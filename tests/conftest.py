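"""Shared fixtures and independent reference implementations.

The reference estimators here are deliberately naive (explicit Python
loops, direct formulas) and share no code with the package: they are the
oracles the vectorized implementations are checked against.
"""

from __future__ import annotations

import numpy as np
import pytest

import parcelsync as ps


# ---------------------------------------------------------------- oracles
def reference_plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Loop-based classic PLV."""
    total = 0j
    for px, py in zip(phase_x, phase_y):
        total += np.exp(1j * (px - py))
    return abs(total / len(phase_x))


def reference_ciplv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Loop-based corrected imaginary PLV."""
    total = 0j
    for px, py in zip(phase_x, phase_y):
        total += np.exp(1j * (px - py))
    c = total / len(phase_x)
    if abs(c.real) >= 1.0 - 1e-12:
        return 0.0
    return abs(c.imag) / np.sqrt(1.0 - c.real**2)


def reference_connectivity(analytic_data: np.ndarray, method: str) -> np.ndarray:
    """Double-loop all-pairs matrix: per-trial statistic, then trial mean."""
    n_trials, n_parcels, _ = analytic_data.shape
    out = np.zeros((n_parcels, n_parcels))
    fn = reference_plv if method == "plv" else reference_ciplv
    for i in range(n_parcels):
        for j in range(n_parcels):
            if i == j:
                out[i, j] = 1.0 if method == "plv" else 0.0
                continue
            vals = []
            for t in range(n_trials):
                vals.append(
                    fn(
                        np.angle(analytic_data[t, i]),
                        np.angle(analytic_data[t, j]),
                    )
                )
            out[i, j] = np.mean(vals)
    return out


@pytest.fixture
def reference_estimators():
    return reference_plv, reference_ciplv, reference_connectivity


# ---------------------------------------------------------------- fixtures
SMALL_CORE = ("core_a", "core_b")
SMALL_SM = ("sm_a", "sm_b")


def small_cohort_config(seed: int, kappa_high: float = 0.8, kappa_low: float = 0.2,
                        n_trials: int = 20) -> ps.CohortConfig:
    """Scaled-down study emulation used by the Monte-Carlo tests:
    2 parcels per system, 20 trials, 1.3 s trials."""
    return ps.CohortConfig(
        n_per_group=7,
        n_trials=n_trials,
        core_set=SMALL_CORE,
        sensorimotor_set=SMALL_SM,
        trial_duration=1.3,
        t0=-0.1,
        coupling_high=kappa_high,
        coupling_low=kappa_low,
        seed=seed,
    )


@pytest.fixture
def small_roi_sets() -> ps.ROISetPair:
    return ps.ROISetPair(sensorimotor=SMALL_SM, core=SMALL_CORE)


@pytest.fixture
def random_analytic():
    """4-parcel, 3-trial random analytic recording (unit-modulus phasors)."""
    rng = np.random.default_rng(42)
    phases = rng.uniform(-np.pi, np.pi, size=(3, 4, 64))
    return ps.AnalyticRecording(
        data=np.exp(1j * phases),
        rate=250.0,
        labels=("p0", "p1", "p2", "p3"),
        band=(13.0, 30.0),
    )


@pytest.fixture
def tone_recording():
    """Pure 20 Hz cosine in two identical parcels, 4 s at 250 Hz."""
    t = np.arange(int(4.0 * 250)) / 250.0
    x = np.cos(2 * np.pi * 20.0 * t)
    data = np.stack([x, x])[np.newaxis]
    return ps.ParcelRecording(data=data, rate=250.0, labels=("a", "b"), t0=0.0)


def run_subject_chain(rec: ps.ParcelRecording,
                      band=(13.0, 30.0), window=(0.0, 1.1), method="ciplv"):
    """The per-subject estimation chain as one helper."""
    filtered = ps.bandpass_filter(rec, *band)
    windowed = ps.select_window(ps.analytic_signal(filtered, band), *window)
    return ps.connectivity_matrix(windowed, method=method)


def write_minimal_edf(path, data: np.ndarray, rate: float, labels) -> None:
    """Write a minimal single-record EDF file (16-bit, one data record).

    ``data`` is channels x samples; samples per record equals the full
    length, record duration ``n_samples / rate`` seconds.
    """
    n_ch, n_samp = data.shape
    duration = n_samp / rate
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("X", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad("1", 8),                       # number of data records
        pad(f"{duration:g}", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        ("".join(str(l).ljust(16)[:16] for l in labels), 16),
        ("Unknown" , 80),
        ("uV", 8),
        (f"{phys_min:g}", 8),
        (f"{phys_max:g}", 8),
        (str(dig_min), 8),
        (str(dig_max), 8),
        ("", 80),
        (str(n_samp), 8),
        ("", 32),
    ]
    body = b""
    for text, width in fields:
        if isinstance(text, str) and len(text) == width * n_ch:
            body += text.encode("ascii")           # pre-joined label block
        else:
            body += pad(text, width) * n_ch
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + body)
        fh.write(digital.tobytes())
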