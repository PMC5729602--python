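"""Exception hierarchy shared across the package."""


class LvFractalError(Exception):
    """Base class for all package errors."""


class InputError(LvFractalError):
    """A file or directory could not be read or understood."""


class ValidationError(LvFractalError, ValueError):
    """An input violated a documented precondition or invariant."""


class SegmentationError(LvFractalError, RuntimeError):
    """Segmentation could not be performed (e.g. no contrast in the ROI)."""
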