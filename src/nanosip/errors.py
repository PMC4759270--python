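"""Typed exceptions raised by nanosip.

Readers and quantifiers never silently coerce bad input; every invariant
violation maps to one of these classes so callers can distinguish, e.g.,
a corrupt TIFF from an ROI label missing from its class table.
"""


class NanosipError(Exception):
    """Base class for all nanosip errors."""


class InvalidArgumentError(NanosipError, ValueError):
    """An argument is outside its documented vocabulary or range."""


class UndefinedRatioError(NanosipError, ZeroDivisionError):
    """Isotope ratio requested for a zero total count."""


class OutOfRangeError(NanosipError, ValueError):
    """A conversion would leave the valid atom-fraction range [0, 1)."""


class PlacementError(NanosipError, RuntimeError):
    """Phantom organelle placement failed after the attempt cap.

    Carries the organelle class name that could not be placed.
    """

    def __init__(self, class_name: str, attempts: int):
        self.class_name = class_name
        self.attempts = attempts
        super().__init__(
            f"could not place organelle of class {class_name!r} "
            f"without overlap after {attempts} attempts"
        )


class DimensionError(NanosipError, ValueError):
    """Image/stack dimensions are mutually inconsistent."""


class FormatError(NanosipError, ValueError):
    """A file violates the format contract (e.g. negative counts)."""


class MissingFileError(NanosipError, FileNotFoundError):
    """A manifest references a file that does not exist."""


class ConsistencyError(NanosipError, ValueError):
    """Manifest metadata disagrees with the file contents."""


class OrphanLabelError(NanosipError, ValueError):
    """A nonzero label in the label image has no class-table row."""

    def __init__(self, labels):
        self.labels = sorted(int(x) for x in labels)
        super().__init__(f"labels present in image but absent from class table: {self.labels}")


class VocabularyError(NanosipError, ValueError):
    """A class name is not in the accepted organelle vocabulary."""


class MissingInputError(NanosipError, ValueError):
    """A required image is missing for the requested analysis."""


class DegenerateVarianceError(NanosipError, ValueError):
    """Rank-test variance is zero (all observations tied)."""


class InsufficientDataError(NanosipError, ValueError):
    """Too few observations for the requested statistic."""


class SchemaError(NanosipError, ValueError):
    """A table is missing required columns."""
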