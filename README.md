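# parcelsync

Beta-band phase-locking connectivity between cortical parcels, the
core-face-system × sensorimotor-system coupling strength, and two-group
inference — with a synthetic coupled-oscillator generator that makes the
whole chain verifiable against known ground truth.

## The problem

Sensorimotor simulation accounts of face perception predict an iterative
exchange between the visual "core system" for faces (fusiform, inferior
occipital, posterior superior temporal sulcus regions) and the motor and
somatosensory cortices. A testable consequence is that people born unable
to produce facial expressions (Moebius syndrome, a congenital palsy of
cranial nerves VI/VII) should show weaker functional coupling between the
two systems while discriminating facial expressions. In parcel-level EEG
source time series this coupling can be quantified by phase synchronization
in the beta band (13–30 Hz) — but classic phase-locking measures are
inflated by volume conduction and source leakage, which mix one underlying
source into many parcels instantaneously and produce spurious zero-lag
synchronization. `parcelsync` implements the estimator that is robust to
this confound and the full analysis built on it.

## The statistic

For two parcels with instantaneous phases φₓ(t), φᵧ(t) over N samples, let

    C = (1/N) Σₜ exp(i·(φₓ(t) − φᵧ(t)))

* **PLV** = |C| — classic phase locking value; 1 under perfect locking at
  *any* lag, including the zero lag produced by leakage.
* **ciPLV** = |Im C| / √(1 − Re C²) — corrected imaginary PLV; discards
  the zero-lag component, so instantaneous mixing cannot inflate it.
  When |Re C| → 1 (perfect zero-lag locking) the value is defined as 0.

Phases come from the Hilbert analytic signal of the 13–30 Hz band-passed
parcel series; the statistic is computed within each trial over the 0–1100
ms window after target onset and averaged across trials, for every pair of
the 148 Destrieux-atlas parcels, giving a symmetric matrix **M**. The
rectangular slice **R** of M (sensorimotor rows × core-system columns) is
summed into the per-subject strength **w = Σᵢⱼ Rᵢⱼ**, and the two groups
are compared with a directional pooled-variance t-test (Cohen's d on the
pooled SD, Shapiro–Wilk normality screens per group).

## Worked example

Simulate a 7-vs-7 cohort in which every sensorimotor parcel is coupled to
a core parcel at a quarter-cycle lag — κ = 0.6 in the control-like group,
κ = 0.3 in the clinical-like group — then run the full chain:

```python
import parcelsync as ps
from parcelsync.model import InterSystemConnectivity

config = ps.CohortConfig(
    n_per_group=7, n_trials=20,
    core_set=("fusiform", "occipital"),
    sensorimotor_set=("precentral", "postcentral"),
    trial_duration=1.3, t0=-0.1,
    coupling_high=0.6, coupling_low=0.3, seed=0,
)
cohort = ps.simulate_group_study(config)
roi = ps.ROISetPair(sensorimotor=config.sensorimotor_set, core=config.core_set)
results = InterSystemConnectivity.from_cohort(
    cohort, roi, group_order=("mbs", "control"), tail="one_sided_less",
).fit()
print(results.summary())
```

```
Inter-system phase-locking connectivity
=======================================================
method: ciplv    band: 13-30 Hz    window: [0, 1.1) s
R: 2 sensorimotor rows x 2 core columns
-------------------------------------------------------
group          n      mean w        SD  Shapiro W       p
mbs            7      0.9780    0.0769      0.912   0.409
control        7      1.4472    0.0724      0.975   0.934
-------------------------------------------------------
t(12) = -11.760   p = 0.0000 (one_sided_less)   d = -6.286
alpha = 0.05: significant
```

Each subject's w sums the 2×2 inter-system slice of their ciPLV matrix;
the lower coupling built into the "mbs" group comes out as a lower mean w
(0.98 vs 1.45), a negative t (the test direction is mbs − control), and a
large negative effect size. Both groups pass the Shapiro–Wilk screen.

The same pipeline is scriptable from the shell and composes stage by
stage (`parcelsync simulate | connect | strength | compare | run`); real
recordings are read from plain numeric matrix directories or EDF files.

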