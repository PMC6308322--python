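"""Exception hierarchy for the pbmshape pipeline."""


class PbmShapeError(Exception):
    """Base class for all pbmshape errors."""


class ConfigurationError(PbmShapeError):
    """Invalid parameter or configuration value."""


class FormatError(PbmShapeError):
    """Malformed curve/metadata file or record."""


class InputError(PbmShapeError):
    """Invalid input data (violated precondition)."""


class AlignmentError(PbmShapeError):
    """Rater traces cannot be aligned (e.g. empty x-overlap)."""


class PlacementError(PbmShapeError):
    """A semi-landmark could not be placed on a curve.

    Attributes
    ----------
    side : str
        "left" or "right" — the branch on which placement failed.
    index : int or None
        The first failing landmark index k on that side (0 = margin).
    """

    def __init__(self, message: str, side: str = "", index: int | None = None):
        super().__init__(message)
        self.side = side
        self.index = index


class EstimationError(PbmShapeError):
    """A statistical model could not be estimated (e.g. singular design)."""


class ClassificationError(PbmShapeError):
    """ROC analysis impossible (e.g. a single class after dichotomization)."""
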