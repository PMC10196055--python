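"""Cohort-level model of inter-system phase-locking connectivity.

:class:`InterSystemConnectivity` is built from a cohort of parcel
recordings with group labels plus the analysis configuration (band,
window, estimator, region sets, test direction).  ``fit()`` runs the full
estimation chain per subject

    band-pass -> analytic signal -> analysis window
    -> all-pairs phase locking -> inter-system slice -> strength w

and then the group comparison, returning a :class:`StudyResults` with the
per-subject strengths, the test, effect size, normality screens, and a
printable summary table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__ as _version
from .connectivity import ConnectivityMatrix, connectivity_matrix
from .errors import DegenerateInputError, LabelError
from .network import (
    InterSystemMatrix,
    ROISetPair,
    connectivity_strength,
    extract_intersystem_matrix,
)
from .recording import ParcelRecording
from .spectral import analytic_signal, bandpass_filter, select_window
from .stats import GroupComparison, independent_t_test

logger = logging.getLogger("parcelsync")


class InterSystemConnectivity:
    """Model: two-group cohort -> inter-system connectivity comparison.

    Parameters
    ----------
    recordings
        One :class:`ParcelRecording` per subject.
    groups
        Group label per subject; exactly two distinct labels.
    roi_sets
        The sensorimotor / core parcel sets defining the rectangular
        inter-system matrix; identical for every subject.
    band
        Pass-band in Hz; default the beta band (13, 30).
    window
        Analysis window in seconds relative to target onset, half-open;
        default (0.0, 1.1).
    method
        ``"ciplv"`` (default) or ``"plv"``.
    tail
        Alternative hypothesis for the group test, applied to
        ``group_order[0] - group_order[1]``; default ``one_sided_less``
        (first group has *lower* strength).
    group_order
        Pair (test group, reference group).  Default: order of first
        appearance in ``groups``.
    subject_ids
        Optional subject identifiers (default ``sub-00`` ...).
    """

    def __init__(
        self,
        recordings,
        groups,
        roi_sets: ROISetPair,
        band: tuple[float, float] = (13.0, 30.0),
        window: tuple[float, float] = (0.0, 1.1),
        method: str = "ciplv",
        tail: str = "one_sided_less",
        alpha: float = 0.05,
        group_order: tuple[str, str] | None = None,
        subject_ids=None,
    ):
        self.recordings = list(recordings)
        self.groups = list(groups)
        if len(self.recordings) != len(self.groups):
            raise DegenerateInputError(
                f"{len(self.recordings)} recordings but {len(self.groups)} group labels"
            )
        if not self.recordings:
            raise DegenerateInputError("empty cohort")
        unique = list(dict.fromkeys(self.groups))  # first-appearance order
        if len(unique) != 2:
            raise DegenerateInputError(
                f"need exactly 2 groups, got {unique}"
            )
        if group_order is None:
            group_order = (unique[0], unique[1])
        if sorted(group_order) != sorted(unique):
            raise LabelError(
                f"group_order {group_order} does not match cohort groups {unique}"
            )
        self.group_order = tuple(group_order)
        self.roi_sets = roi_sets
        self.band = (float(band[0]), float(band[1]))
        self.window = (float(window[0]), float(window[1]))
        self.method = method
        self.tail = tail
        self.alpha = float(alpha)
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else [f"sub-{i:02d}" for i in range(len(self.recordings))]
        )
        if len(self.subject_ids) != len(self.recordings):
            raise DegenerateInputError("subject_ids length mismatch")
        for sid, rec in zip(self.subject_ids, self.recordings):
            try:
                roi_sets.validate_against(rec.labels)
            except LabelError as exc:
                raise LabelError(f"subject {sid!r}: {exc}") from exc

    @classmethod
    def from_cohort(cls, cohort, roi_sets: ROISetPair, **kwargs):
        """Build from an iterable of ``(recording, group_label)`` pairs,
        e.g. the output of :func:`parcelsync.synthetic.simulate_group_study`."""
        recs, groups = zip(*cohort)
        return cls(recs, groups, roi_sets, **kwargs)

    def _subject_strength(
        self, rec: ParcelRecording, subject: str
    ) -> tuple[float, ConnectivityMatrix, InterSystemMatrix]:
        logger.debug("%s: bandpass %s Hz", subject, self.band)
        filtered = bandpass_filter(rec, *self.band)
        analytic = analytic_signal(filtered, self.band)
        windowed = select_window(analytic, *self.window)
        logger.debug(
            "%s: %d samples in window, estimating %s",
            subject,
            windowed.n_samples,
            self.method,
        )
        m = connectivity_matrix(windowed, method=self.method)
        r = extract_intersystem_matrix(m, self.roi_sets)
        return connectivity_strength(r), m, r

    def fit(self, keep_matrices: bool = False) -> "StudyResults":
        """Run the full chain and the group test.

        Parameters
        ----------
        keep_matrices
            If True, retain each subject's full connectivity matrix and
            inter-system slice on the results object.
        """
        strengths: list[float] = []
        matrices: dict[str, ConnectivityMatrix] = {}
        intersystem: dict[str, InterSystemMatrix] = {}
        for subject, rec, group in zip(self.subject_ids, self.recordings, self.groups):
            try:
                w, m, r = self._subject_strength(rec, subject)
            except Exception as exc:
                raise type(exc)(f"subject {subject!r}: {exc}") from exc
            logger.info("%s (%s): w = %.4f", subject, group, w)
            strengths.append(w)
            if keep_matrices:
                matrices[subject] = m
                intersystem[subject] = r
        frame = pd.DataFrame(
            {
                "subject": self.subject_ids,
                "group": self.groups,
                "strength": strengths,
            }
        )
        a_label, b_label = self.group_order
        a = frame.loc[frame["group"] == a_label, "strength"].to_numpy()
        b = frame.loc[frame["group"] == b_label, "strength"].to_numpy()
        comparison = independent_t_test(a, b, tail=self.tail)
        return StudyResults(
            model=self,
            strengths=frame,
            comparison=comparison,
            matrices=matrices if keep_matrices else None,
            intersystem=intersystem if keep_matrices else None,
        )


class StudyResults:
    """Fitted results: per-subject strengths and the group comparison."""

    def __init__(
        self,
        model: InterSystemConnectivity,
        strengths: pd.DataFrame,
        comparison: GroupComparison,
        matrices=None,
        intersystem=None,
    ):
        self.model = model
        self.strengths = strengths
        self.comparison = comparison
        self.matrices = matrices
        self.intersystem = intersystem

    @property
    def group_summary(self) -> pd.DataFrame:
        """Per-group n, mean, and SD of the strength w."""
        g = self.strengths.groupby("group", sort=False)["strength"]
        return g.agg(n="count", mean="mean", sd="std")

    @property
    def significant(self) -> bool:
        return self.comparison.p < self.model.alpha

    def provenance(self) -> dict:
        cfg = {
            "band": self.model.band,
            "window": self.model.window,
            "method": self.model.method,
            "tail": self.model.tail,
            "alpha": self.model.alpha,
            "group_order": self.model.group_order,
            "sensorimotor": self.model.roi_sets.sensorimotor,
            "core": self.model.roi_sets.core,
            "subjects": self.model.subject_ids,
            "groups": self.model.groups,
        }
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=list).encode()
        ).hexdigest()
        return {"config_hash": digest, "version": _version, "config": cfg}

    def to_dict(self) -> dict:
        c = self.comparison
        return {
            "strengths": self.strengths.to_dict(orient="records"),
            "group_order": list(self.model.group_order),
            "comparison": asdict(c),
            "provenance": self.provenance(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=list)

    def summary(self) -> str:
        """Human-readable study summary table."""
        c = self.comparison
        a, b = self.model.group_order
        lines = [
            "Inter-system phase-locking connectivity",
            "=" * 55,
            f"method: {self.model.method}    band: {self.model.band[0]:g}-"
            f"{self.model.band[1]:g} Hz    window: [{self.model.window[0]:g}, "
            f"{self.model.window[1]:g}) s",
            f"R: {len(self.model.roi_sets.sensorimotor)} sensorimotor rows x "
            f"{len(self.model.roi_sets.core)} core columns",
            "-" * 55,
            f"{'group':<12}{'n':>4}{'mean w':>12}{'SD':>10}{'Shapiro W':>11}{'p':>8}",
        ]
        for label, n, mean, sd, sh in zip(
            (a, b),
            c.group_ns,
            c.group_means,
            c.group_sds,
            c.shapiro,
        ):
            shw = f"{sh[0]:.3f}" if sh else "--"
            shp = f"{sh[1]:.3f}" if sh else "--"
            lines.append(f"{label:<12}{n:>4}{mean:>12.4f}{sd:>10.4f}{shw:>11}{shp:>8}")
        lines += [
            "-" * 55,
            f"t({c.df}) = {c.t:.3f}   p = {c.p:.4f} ({c.tail})   d = {c.d:.3f}",
            f"alpha = {self.model.alpha:g}: "
            + ("significant" if self.significant else "not significant"),
        ]
        return "\n".join(lines)

    def plot_strengths(self, ax=None):
        """Strip plot of per-subject strengths by group (returns the axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        rng = np.random.default_rng(0)
        for i, group in enumerate(self.model.group_order):
            vals = self.strengths.loc[
                self.strengths["group"] == group, "strength"
            ].to_numpy()
            x = i + rng.uniform(-0.08, 0.08, size=vals.size)
            ax.plot(x, vals, "o", alpha=0.7, label=group)
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k", lw=2)
        ax.set_xticks(range(len(self.model.group_order)))
        ax.set_xticklabels(self.model.group_order)
        ax.set_ylabel("inter-system strength w")
        return ax
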