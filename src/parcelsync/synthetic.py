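"""Synthetic narrowband parcel recordings with known coupling structure.

The generator produces beta-range oscillatory "parcel" signals whose
pairwise phase coupling, coupling lag, and instantaneous cross-parcel
mixing (the volume-conduction / source-leakage surrogate) are all under
explicit control, so the connectivity estimators downstream can be checked
against a known truth.

Each parcel starts from an independent unit-variance narrowband noise
process (white noise band-pass filtered around the oscillator's center
frequency).  A coupling of strength ``kappa`` from source ``s`` to target
``t`` with lag ``tau`` replaces the target's latent trace by

    x_t  =  kappa * x_s(t - tau)  +  sqrt(1 - kappa**2) * x_t_own

so the marginal variance of every parcel is independent of ``kappa`` and
the phase-locking between the pair grows monotonically with it.  The lag is
applied as an exact (possibly fractional-sample) delay in the frequency
domain; a zero lag is a literal copy.  Instantaneous mixing is a separate
operator applied sample-wise after generation.

The two-group study emulator builds a cohort of 2 x ``n_per_group``
subjects in which every sensorimotor parcel is phase-coupled to a core
face-system parcel at a quarter-cycle lag; the control-like group uses
``coupling_high`` and the clinical-like ("mbs") group ``coupling_low``,
emulating reduced core-to-sensorimotor communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .atlas import DEFAULT_CORE, DEFAULT_SENSORIMOTOR
from .errors import (
    CouplingError,
    DegenerateInputError,
    DimensionError,
    LabelError,
)
from .recording import ParcelRecording


@dataclass(frozen=True)
class OscillatorSpec:
    """Narrowband oscillator: band-limited noise around ``center_freq``.

    ``phase_noise_sd`` adds a per-sample random-walk phase jitter (radians)
    on top of the intrinsic phase diffusion of the filtered noise.
    """

    center_freq: float = 20.0
    bandwidth: float = 6.0
    amplitude: float = 1.0
    phase_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.bandwidth < self.center_freq:
            raise DegenerateInputError(
                f"need 0 < bandwidth < center_freq, got "
                f"bw={self.bandwidth}, f0={self.center_freq}"
            )
        if self.amplitude <= 0:
            raise DegenerateInputError(f"amplitude must be > 0, got {self.amplitude}")
        if self.phase_noise_sd < 0:
            raise DegenerateInputError("phase_noise_sd must be >= 0")

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2.0,
                self.center_freq + self.bandwidth / 2.0)

    def quarter_cycle(self) -> float:
        """Lag (s) of a quarter period at the center frequency."""
        return 0.25 / self.center_freq


@dataclass(frozen=True)
class CouplingSpec:
    """Directed phase coupling from ``source`` into ``target``."""

    source: str
    target: str
    strength: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise CouplingError(f"self-coupling on {self.source!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise CouplingError(f"strength must be in [0, 1], got {self.strength}")


def _narrowband_base(
    rng: np.random.Generator,
    n_trials: int,
    n_padded: int,
    rate: float,
    spec: OscillatorSpec,
) -> np.ndarray:
    """Unit-variance narrowband noise, shape (n_trials, n_padded)."""
    low, high = spec.band
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_trials, n_padded)), axis=-1)
    if spec.phase_noise_sd > 0:
        jitter = np.cumsum(
            rng.normal(0.0, spec.phase_noise_sd, size=x.shape), axis=-1
        )
        x = np.real(sps.hilbert(x, axis=-1) * np.exp(1j * jitter))
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _fractional_delay(x: np.ndarray, lag_s: float, rate: float) -> np.ndarray:
    """Exact delay by ``lag_s`` seconds along the last axis (circular in the
    padded domain; callers keep the pad wide enough that wrap-around never
    reaches the retained segment)."""
    if lag_s == 0.0:
        return x.copy()
    n = x.shape[-1]
    f = np.fft.rfftfreq(n, 1.0 / rate)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * np.exp(-2j * np.pi * f * lag_s), n, axis=-1)


def simulate_parcel_timeseries(
    specs: Mapping[str, OscillatorSpec],
    couplings: Sequence[CouplingSpec] = (),
    n_trials: int = 50,
    duration: float = 1.5,
    rate: float = 250.0,
    seed: int = 0,
    t0: float = 0.0,
) -> ParcelRecording:
    """Generate coupled narrowband parcel signals.

    Parameters
    ----------
    specs
        Ordered mapping parcel label -> :class:`OscillatorSpec`.
    couplings
        Directed couplings; a parcel may be the target of several couplings
        provided the total coupled energy ``sum(kappa**2)`` stays <= 1, and
        a coupling target may not itself be a source (no chains).
    n_trials, duration, rate, seed, t0
        Trial count, trial length (s), sampling rate (Hz), RNG seed, and
        time of the first sample relative to target onset (s).

    Returns
    -------
    ParcelRecording
        Shape ``(n_trials, len(specs), round(duration * rate))``;
        deterministic given ``seed``.
    """
    labels = tuple(specs)
    if not labels:
        raise DegenerateInputError("need at least one parcel spec")
    n = int(round(duration * rate))
    if n < 8:
        raise DegenerateInputError(
            f"duration * rate = {duration * rate:.1f} gives fewer than 8 samples"
        )
    max_f0 = max(s.center_freq for s in specs.values())
    if rate <= 2.0 * max_f0:
        raise DegenerateInputError(
            f"rate {rate} Hz must exceed twice the highest center frequency ({max_f0} Hz)"
        )
    for c in couplings:
        for lab in (c.source, c.target):
            if lab not in labels:
                raise LabelError(f"coupling references unknown parcel {lab!r}")
    targets = {c.target for c in couplings}
    sources = {c.source for c in couplings}
    if targets & sources:
        raise CouplingError(
            f"coupling chains not supported: {sorted(targets & sources)} "
            "appear as both source and target"
        )
    by_target: dict[str, list[CouplingSpec]] = {}
    for c in couplings:
        by_target.setdefault(c.target, []).append(c)
    for tgt, cs in by_target.items():
        energy = sum(c.strength**2 for c in cs)
        if energy > 1.0 + 1e-12:
            raise CouplingError(
                f"total coupled energy into {tgt!r} is {energy:.3f} > 1"
            )

    # pad with >= 1 s on each side: covers filter warm-up and delay wrap
    max_lag = max((abs(c.lag) for c in couplings), default=0.0)
    pad = int(np.ceil(rate * max(1.0, 2.0 * max_lag)))
    n_padded = n + 2 * pad

    rng = np.random.default_rng(seed)
    base = np.empty((n_trials, len(labels), n_padded))
    for p, lab in enumerate(labels):
        base[:, p, :] = _narrowband_base(rng, n_trials, n_padded, rate, specs[lab])

    out = base.copy()
    for tgt, cs in by_target.items():
        ti = labels.index(tgt)
        energy = sum(c.strength**2 for c in cs)
        mix = np.sqrt(max(0.0, 1.0 - energy)) * base[:, ti, :]
        for c in cs:
            si = labels.index(c.source)
            mix = mix + c.strength * _fractional_delay(base[:, si, :], c.lag, rate)
        out[:, ti, :] = mix

    out = out[:, :, pad : pad + n]
    amps = np.array([specs[lab].amplitude for lab in labels])
    out = out * amps[None, :, None]
    return ParcelRecording(data=out, rate=rate, labels=labels, t0=t0)


def apply_instantaneous_mixing(rec: ParcelRecording, weights: np.ndarray) -> ParcelRecording:
    """Apply a zero-lag linear mixing matrix to every sample.

    ``observed[:, i, t] = sum_j weights[i, j] * rec.data[:, j, t]`` — the
    standard surrogate for volume conduction / source leakage.  An identity
    matrix returns the input unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionError(f"mixing matrix must be square, got shape {w.shape}")
    if w.shape[0] != rec.n_parcels:
        raise DimensionError(
            f"mixing is {w.shape[0]}x{w.shape[1]} but recording has "
            f"{rec.n_parcels} parcels"
        )
    mixed = np.einsum("ij,tjs->tis", w, rec.data)
    return rec.with_data(mixed)


@dataclass(frozen=True)
class CohortConfig:
    """Study-emulation configuration: two groups of coupled-oscillator subjects.

    Defaults mirror the emulated study design: 7 subjects per group, 250 Hz
    sampling, trials spanning -0.2..1.3 s around target onset (so the
    0-1100 ms analysis window fits inside), beta oscillators at 20 Hz with
    6 Hz bandwidth, and between-system couplings at a quarter-cycle lag.
    ``coupling_high`` drives the control-like group, ``coupling_low`` the
    clinical-like group.  Trial count per subject is a free parameter of
    the emulation (the emulated study does not publish one); default 50.
    """

    n_per_group: int = 7
    n_trials: int = 50
    sampling_rate: float = 250.0
    trial_duration: float = 1.5
    t0: float = -0.2
    core_set: tuple[str, ...] = DEFAULT_CORE
    sensorimotor_set: tuple[str, ...] = DEFAULT_SENSORIMOTOR
    coupling_high: float = 0.8
    coupling_low: float = 0.2
    oscillator: OscillatorSpec = field(default_factory=OscillatorSpec)
    lag: float | None = None  # None -> quarter cycle at oscillator center
    seed: int = 0
    group_labels: tuple[str, str] = ("control", "mbs")

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_set", tuple(self.core_set))
        object.__setattr__(self, "sensorimotor_set", tuple(self.sensorimotor_set))
        if self.n_per_group < 2:
            raise DegenerateInputError("n_per_group must be >= 2")
        if not self.core_set or not self.sensorimotor_set:
            raise LabelError("core and sensorimotor sets must be nonempty")
        overlap = set(self.core_set) & set(self.sensorimotor_set)
        if overlap:
            raise LabelError(f"core/sensorimotor sets overlap: {sorted(overlap)}")
        if self.coupling_high < self.coupling_low:
            raise CouplingError("coupling_high must be >= coupling_low")
        for kappa in (self.coupling_high, self.coupling_low):
            if not 0.0 <= kappa <= 1.0:
                raise CouplingError(f"coupling strength {kappa} outside [0, 1]")

    @property
    def n_parcels(self) -> int:
        return len(self.core_set) + len(self.sensorimotor_set)

    @property
    def parcels(self) -> tuple[str, ...]:
        return self.core_set + self.sensorimotor_set

    @property
    def effective_lag(self) -> float:
        return self.oscillator.quarter_cycle() if self.lag is None else self.lag

    def couplings(self, strength: float) -> tuple[CouplingSpec, ...]:
        """Between-system couplings: each sensorimotor parcel locked to a
        core parcel (round-robin) at the configured lag."""
        lag = self.effective_lag
        return tuple(
            CouplingSpec(
                source=self.core_set[i % len(self.core_set)],
                target=sm,
                strength=strength,
                lag=lag,
            )
            for i, sm in enumerate(self.sensorimotor_set)
        )


def simulate_group_study(config: CohortConfig) -> list[tuple[ParcelRecording, str]]:
    """Simulate a full two-group cohort.

    Returns ``2 * n_per_group`` pairs ``(recording, group_label)``: first
    the control-like subjects (between-system coupling ``coupling_high``),
    then the clinical-like subjects (``coupling_low``).  Subject ``k`` uses
    seed ``config.seed + k``, so cohorts are reproducible and subjects
    within a group differ only by their noise realization.
    """
    specs = {lab: config.oscillator for lab in config.parcels}
    cohort: list[tuple[ParcelRecording, str]] = []
    group_kappa = (
        (config.group_labels[0], config.coupling_high),
        (config.group_labels[1], config.coupling_low),
    )
    subject = 0
    for group, kappa in group_kappa:
        for _ in range(config.n_per_group):
            rec = simulate_parcel_timeseries(
                specs,
                couplings=config.couplings(kappa),
                n_trials=config.n_trials,
                duration=config.trial_duration,
                rate=config.sampling_rate,
                seed=config.seed + subject,
                t0=config.t0,
            )
            cohort.append((rec, group))
            subject += 1
    return cohort


def leakage_demo_recording(
    seed: int = 0,
    shared_weights: tuple[float, float] = (1.0, 0.8),
    noise_weight: float = 0.15,
    n_trials: int = 50,
    duration: float = 10.0,
    rate: float = 250.0,
    oscillator: OscillatorSpec | None = None,
) -> ParcelRecording:
    """Two observed channels dominated by one shared latent source.

    Three independent latent oscillators (the shared source plus one weak
    background process per channel) are mixed instantaneously so that
    channel ``i = shared_weights[i] * source + noise_weight * background_i``.
    With the default weights the channels are almost pure copies of the
    source: classic PLV between them is driven close to 1 by the zero-lag
    leakage while ciPLV stays near its noise floor.  Only the first two
    parcels (``"ch1"``, ``"ch2"``) are the observed channels; the third
    row of the returned recording is the untouched second background
    process and is ignored by callers.
    """
    osc = oscillator or OscillatorSpec()
    latent = simulate_parcel_timeseries(
        {"src": osc, "bg1": osc, "bg2": osc},
        couplings=(),
        n_trials=n_trials,
        duration=duration,
        rate=rate,
        seed=seed,
    )
    a, b = shared_weights
    mixing = np.array(
        [
            [a, noise_weight, 0.0],
            [b, 0.0, noise_weight],
            [0.0, 0.0, 1.0],
        ]
    )
    mixed = apply_instantaneous_mixing(latent, mixing)
    return ParcelRecording(
        data=mixed.data[:, :2, :],
        rate=rate,
        labels=("ch1", "ch2"),
        t0=mixed.t0,
    )
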