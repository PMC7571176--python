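"""Exception hierarchy for the ramanpen pipeline."""


class RamanPenError(Exception):
    """Base class for all package errors."""


class ScanFormatError(RamanPenError):
    """A scan or config file is malformed (bad header, unknown keys)."""


class ValidationError(RamanPenError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class SurfaceDetectionError(RamanPenError):
    """The keratin profile never crosses half of its maximum."""


class ProfileShapeError(RamanPenError):
    """A profile does not have the shape an operation requires (e.g. no peak)."""
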