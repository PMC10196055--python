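"""Exception hierarchy.

Every validation failure in the pipeline raises a subclass of
:class:`ParcelSyncError`, so callers can distinguish bad input from bugs.
"""


class ParcelSyncError(ValueError):
    """Base class for all labeled pipeline errors."""


class LabelError(ParcelSyncError):
    """A parcel label is unknown, duplicated, or inconsistent."""


class DegenerateInputError(ParcelSyncError):
    """Input too short, constant, or otherwise carries no information."""


class BandError(ParcelSyncError):
    """Frequency band outside (0, Nyquist) or inverted."""


class WindowError(ParcelSyncError):
    """Analysis window does not intersect the recording's time axis."""


class DimensionError(ParcelSyncError):
    """Array dimensions do not match (mixing matrix, paired phases...)."""


class CouplingError(ParcelSyncError):
    """Inconsistent coupling specification (self-coupling, chains, energy > 1)."""


class SidecarError(ParcelSyncError):
    """Recording sidecar metadata missing or inconsistent with the data."""
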