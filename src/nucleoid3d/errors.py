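"""Exception types shared across the package."""


class MatrixFormatError(ValueError):
    """A contact-matrix (or coordinate) file could not be parsed."""


class DimensionError(ValueError):
    """Input dimensions are inconsistent with the genome binning."""


class EmptyMatrixError(ValueError):
    """Every bin was masked; there is nothing left to operate on."""


class EmbeddingError(RuntimeError):
    """The contact matrix is too degenerate to embed in 3D."""


class CapacityError(RuntimeError):
    """A synthetic image field is too small for the requested cells."""
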