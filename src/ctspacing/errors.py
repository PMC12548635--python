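"""Exception hierarchy for slice-spacing QC failures."""


class CTSpacingError(Exception):
    """Base class for all errors raised by this package."""


class SeriesTooSmallError(CTSpacingError):
    """Fewer than two usable slices in a series directory."""


class IncompleteGeometryError(CTSpacingError):
    """A slice is missing position or orientation metadata."""


class NonParallelSlicesError(CTSpacingError):
    """Slice normals within one series disagree beyond tolerance."""


class UnknownSpecimenError(CTSpacingError):
    """Specimen identifier outside the catalogued W001-W985 range."""


class DegeneratePairingError(CTSpacingError):
    """Paired samples are identical; the paired t-statistic is undefined."""


class InvalidGridError(CTSpacingError):
    """Non-positive voxel spacing supplied to a distance computation."""


class FiducialOutOfBoundsError(CTSpacingError):
    """A requested phantom fiducial lies outside the volume extent."""
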