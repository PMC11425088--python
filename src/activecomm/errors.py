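"""Exception hierarchy for activecomm."""


class ActivecommError(Exception):
    """Base class for all package-specific errors."""


class PoseFormatError(ActivecommError):
    """A pose or annotation file does not match any supported dialect."""


class StreamError(ActivecommError):
    """A pose stream violates its invariants (e.g. non-monotone frame index)."""


class DegeneratePoseError(ActivecommError):
    """Head and tailbase coincide; no heading direction is defined."""


class OutOfArenaError(ActivecommError):
    """A position falls outside the arena beyond tolerance."""


class ParameterError(ActivecommError):
    """A parameter combination is infeasible or inconsistent."""


class SeparabilityError(ActivecommError):
    """Blue/green frame populations are not separable by mean intensity."""


class BaselineError(ActivecommError):
    """A DF/F baseline is non-positive inside the brain mask."""


class AlignmentError(ActivecommError):
    """Annotations reference frames absent from the prediction stream."""


class PipelineOrderError(ActivecommError):
    """A preprocessing stage was requested out of order."""
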