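"""Exception types shared across the pipeline."""


class SanmapError(ValueError):
    """Base class for all package-specific errors."""


class GeometryError(SanmapError):
    """Phantom geometry is inconsistent (e.g. SAN ellipse outside the tissue block)."""


class ProtocolError(SanmapError):
    """An acquisition protocol is invalid or incompatible with the data."""


class DegenerateInputError(SanmapError):
    """Input carries too little structure for the requested operation
    (constant image, fewer distinct values than classes, empty mask)."""
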