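"""Exception types shared across the package."""


class AnacomError(Exception):
    """Base class for package errors."""


class GridMismatchError(AnacomError):
    """Two volumes do not live on the same standard-space grid.

    The message names both affines so the offending file can be found.
    """


class MaskFormatError(AnacomError):
    """A volume cannot be interpreted as a binary lesion mask."""


class SpecError(AnacomError):
    """An invalid simulation or run configuration."""
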