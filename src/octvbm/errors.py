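"""Exception hierarchy for the VBM-OCT pipeline.

Every stage raises a subclass of :class:`OctVbmError` so callers (and the
CLI) can abort with the stage name and the offending input.
"""


class OctVbmError(Exception):
    """Base class for all pipeline errors."""


class MetadataError(OctVbmError):
    """Required sidecar metadata (layer, laterality, geometry) is missing."""


class GeometryError(OctVbmError):
    """Array dimensions are inconsistent with the declared scan geometry."""


class LateralityError(OctVbmError):
    """Laterality is unknown or unsupported for the requested operation."""


class SegmentationError(OctVbmError):
    """Boundary surfaces violate the anatomical order at a valid A-line."""


class DegenerateInputError(OctVbmError):
    """Input is degenerate for the operation (zero variance, zero span...)."""


class FoveaError(OctVbmError):
    """No fovea can be located (e.g. all-invalid retina map)."""


class StackError(OctVbmError):
    """Group-stack construction received inconsistent maps."""


class DesignError(OctVbmError):
    """The GLM design matrix is unusable (rank deficient everywhere...)."""


class SessionError(OctVbmError):
    """Retest stack has the wrong number of sessions for the operation."""


class ConfigError(OctVbmError):
    """Pipeline configuration is invalid."""
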