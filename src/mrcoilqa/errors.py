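"""Exception hierarchy for the QA pipeline."""


class QaError(Exception):
    """Base class for all package errors."""


class FormatError(QaError):
    """Input file is not in a supported/parsable format."""


class ValidationError(QaError):
    """Input parsed but violates a hard structural expectation."""


class DegenerateInputError(QaError):
    """Input is technically valid but carries no usable information
    (constant image, all-zero signal, zero noise SD)."""


class SegmentationError(QaError):
    """Phantom segmentation produced no usable mask."""


class GeometryError(QaError):
    """An ROI cannot be placed as requested (out of bounds, empty mask)."""


class ClassificationError(QaError):
    """A coil-element label does not match the element grammar."""
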