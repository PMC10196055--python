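"""Inter-system slice of the connectivity matrix and its summed strength.

From the full symmetric parcels x parcels matrix M, the analysis extracts
the rectangular submatrix R whose rows are the sensorimotor parcels and
whose columns are the core face-system parcels; the scalar outcome per
subject is the sum of all entries of R,

    w = sum_{i,j} R[i, j]

Note that w is a *sum*, not a mean: it scales with the sizes of the two
region sets, so group comparisons are only meaningful when every subject
uses the identical :class:`ROISetPair` (the pipeline enforces this by
construction).  The two sets must be disjoint — any overlap would place
self-connectivity (diagonal) entries into w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import DegenerateInputError, LabelError


@dataclass(frozen=True)
class ROISetPair:
    """The two disjoint parcel sets of the inter-system analysis.

    ``sensorimotor`` indexes the rows of R, ``core`` the columns.
    """

    sensorimotor: tuple[str, ...]
    core: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensorimotor", tuple(self.sensorimotor))
        object.__setattr__(self, "core", tuple(self.core))
        if not self.sensorimotor or not self.core:
            raise LabelError("both parcel sets must be nonempty")
        for name, labels in (("sensorimotor", self.sensorimotor), ("core", self.core)):
            if len(set(labels)) != len(labels):
                raise LabelError(f"duplicate labels in {name} set")
        overlap = set(self.sensorimotor) & set(self.core)
        if overlap:
            raise LabelError(
                f"sensorimotor and core sets overlap: {sorted(overlap)}"
            )

    def validate_against(self, atlas_labels) -> None:
        """Raise LabelError listing every label absent from ``atlas_labels``."""
        known = set(atlas_labels)
        missing = [l for l in self.sensorimotor + self.core if l not in known]
        if missing:
            raise LabelError(f"labels not present in the atlas: {missing}")


@dataclass(frozen=True)
class InterSystemMatrix:
    """Rectangular sensorimotor x core slice of a connectivity matrix.

    ``strength_w`` is always recomputed from ``values`` at construction.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    strength_w: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if v.ndim != 2 or v.size == 0:
            raise DegenerateInputError(f"R must be a nonempty 2-D matrix, got {v.shape}")
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise LabelError(
                f"label counts {len(self.row_labels)}x{len(self.col_labels)} "
                f"do not match matrix shape {v.shape}"
            )
        object.__setattr__(self, "strength_w", float(v.sum()))


def extract_intersystem_matrix(
    m: ConnectivityMatrix, sets: ROISetPair
) -> InterSystemMatrix:
    """Slice M into R: sensorimotor rows x core columns, in the given order."""
    sets.validate_against(m.labels)
    index = {lab: i for i, lab in enumerate(m.labels)}
    rows = [index[l] for l in sets.sensorimotor]
    cols = [index[l] for l in sets.core]
    return InterSystemMatrix(
        values=m.values[np.ix_(rows, cols)],
        row_labels=sets.sensorimotor,
        col_labels=sets.core,
    )


def connectivity_strength(r: InterSystemMatrix) -> float:
    """Summed inter-system connectivity strength w = sum_{i,j} R[i, j]."""
    return float(np.sum(r.values))
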