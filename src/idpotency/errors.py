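"""Exception hierarchy shared across the package.

All domain errors derive from :class:`IDPotencyError` so that callers (and
the command-line layer) can distinguish data/model problems from bugs.
"""


class IDPotencyError(Exception):
    """Base class for all domain errors raised by idpotency."""


class FormatError(IDPotencyError):
    """An input file violates its declared on-disk format."""


class EmptyFilterError(IDPotencyError):
    """Cell filtering removed every cell."""


class GeneSelectionError(IDPotencyError):
    """The requested gene list does not intersect the matrix genes."""


class NormalizationError(IDPotencyError):
    """Relative-abundance normalization is undefined (zero-total cell)."""


class DegenerateCloudError(IDPotencyError):
    """A point cloud is too small or too collapsed for neighbor statistics."""


class EstimatorError(IDPotencyError):
    """An intrinsic-dimension estimator hit a degenerate configuration."""


class GroupTooSmallError(IDPotencyError):
    """A cell group is too small to support subsampled ID estimation."""


class DegenerateRangeError(IDPotencyError):
    """Min-max rescaling is undefined (fewer than two distinct means).

    The raw per-group results are attached as ``results`` so callers can
    still report unscaled IDs.
    """

    def __init__(self, message, results=None):
        super().__init__(message)
        self.results = results


class AlignmentError(IDPotencyError):
    """Two per-cell tables do not share the same cell identifiers."""


class CapacityError(IDPotencyError):
    """A Hopfield model was requested above its storage capacity."""


class ConfigError(IDPotencyError):
    """Invalid parameter combination for an operation."""
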