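"""Exception types raised across the package."""


class MorphAssignError(Exception):
    """Base class for package errors."""


class FormatError(MorphAssignError):
    """A file could not be parsed in the expected format."""


class UnsupportedFormatError(FormatError):
    """The file parsed but uses a feature outside the supported subset."""


class EmptyModelError(MorphAssignError):
    """An operation received a model with no usable protein residues."""


class OutOfBoundsError(MorphAssignError):
    """A coordinate fell outside the density-map bounding box."""
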