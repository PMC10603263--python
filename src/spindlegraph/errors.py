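"""Exception hierarchy for spindlegraph."""


class SpindleGraphError(Exception):
    """Base class for all spindlegraph errors."""


class AmiraFormatError(SpindleGraphError):
    """The input is not a readable AmiraMesh ASCII HxSpatialGraph document.

    Raised for malformed headers, binary files, unparseable declarations or
    data blocks. The message names the offending line where possible.
    """


class AmiraStructureError(SpindleGraphError):
    """The document parsed, but its declared counts or indices are inconsistent."""


class GeometryError(SpindleGraphError):
    """A geometric precondition is violated (coincident poles, <2 points, ...)."""
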