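"""Exception hierarchy shared across the pipeline."""


class KatyjumpError(Exception):
    """Base class for all package errors."""


class TrajectoryFormatError(KatyjumpError):
    """A trajectory file could not be parsed or violates an invariant."""


class EventDetectionError(KatyjumpError):
    """A jump event (take-off, contact, stationary) could not be located."""


class DegenerateGeometryError(KatyjumpError):
    """Coincident landmarks make an angle or axis undefined."""


class PureTranslationError(KatyjumpError):
    """Beam model with zero moment arm: linear/angular coupling is infinite."""


class UnreachableTargetError(KatyjumpError):
    """Ballistics: the take-off speed cannot carry the body to the target."""
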