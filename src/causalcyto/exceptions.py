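"""Exception hierarchy shared across the package."""


class CausalCytoError(Exception):
    """Base class for all package errors."""


class ValidationError(CausalCytoError):
    """Input fails a contract (non-finite values, wrong range, bad label)."""


class ShapeError(CausalCytoError):
    """Array has the wrong shape for the requested operation."""


class PairingError(CausalCytoError):
    """Sample matrices that must share n do not."""


class ConfigurationError(CausalCytoError):
    """Invalid configuration value (permutation count, split fractions, ...)."""


class SegmentationError(CausalCytoError):
    """Cell segmentation produced an empty nucleus or cytoplasm."""


class DataError(CausalCytoError):
    """Dataset-level problem (empty split, class too small, missing file)."""
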