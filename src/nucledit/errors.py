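"""Exception hierarchy.

All data-level failures derive from :class:`NucleditError` so the CLI can map
them to a single exit code, distinct from usage errors.
"""


class NucleditError(Exception):
    """Base class for all data-level errors raised by this package."""


class FormatError(NucleditError):
    """A file could not be read or written in the requested format."""


class ShapeMismatchError(NucleditError):
    """Two volumes (or slices of a stack) do not have compatible shapes."""


class ValidationError(NucleditError):
    """An input value violates a documented invariant."""


class DegenerateInputError(NucleditError):
    """The input admits no meaningful answer (e.g. constant-intensity volume)."""


class MetadataParseError(FormatError):
    """The JSON region-status sidecar is malformed."""


class UnknownLabelError(NucleditError):
    """A requested label is not present in the label volume."""


class InvalidSelectionError(NucleditError):
    """The selected voxel is invalid for the requested edit."""


class RegionUnreachableError(NucleditError):
    """The target region has no voxels in the selected slice."""


class SplitInfeasibleError(NucleditError):
    """No intensity threshold separates the region into the requested count."""
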