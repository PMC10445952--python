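"""Exception hierarchy.

All package-specific failures derive from :class:`MitopopError` so callers
can catch one base class at pipeline boundaries.
"""


class MitopopError(Exception):
    """Base class for all mitopop errors."""


class AlignmentShapeError(MitopopError):
    """Rows of an alignment have unequal lengths, or the alignment is empty."""


class DuplicateNameError(MitopopError):
    """Two records share an identifier."""


class AlphabetError(MitopopError):
    """A sequence contains characters outside {A,C,G,T,-,N}."""


class CoordinateError(MitopopError):
    """A 1-based inclusive coordinate is out of range or inverted."""


class OrderingError(MitopopError):
    """Features passed where genome order (sorted by start) is required."""


class EmptyInputError(MitopopError):
    """No usable characters remain after filtering gaps/N."""


class DegenerateAlignmentError(MitopopError):
    """No alignment columns survive the gap policy."""


class SampleSizeError(MitopopError):
    """Fewer sequences than the statistic requires."""


class SaturationError(MitopopError):
    """A pairwise distance correction received a non-positive log argument."""


class EstimationError(MitopopError):
    """A substitution-model fit is impossible on the given data."""


class NoAmpliconError(MitopopError):
    """In-silico PCR found no product."""


class AmbiguousAmpliconError(MitopopError):
    """In-silico PCR found more than one product.

    The candidate products are carried in ``.amplicons``.
    """

    def __init__(self, message, amplicons):
        super().__init__(message)
        self.amplicons = list(amplicons)


class PlacementError(MitopopError):
    """Two planted elements of a synthetic genome disagree where they overlap."""


class TreeSizeError(MitopopError):
    """Fewer than three taxa for tree construction."""
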