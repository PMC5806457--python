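"""Exception hierarchy shared across the package."""


class LeafAgreeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(LeafAgreeError, ValueError):
    """A study design request is malformed (non-positive sizes, unknown variants)."""


class ConfigurationError(LeafAgreeError, ValueError):
    """A configuration value is missing, unknown or inconsistent."""


class InvalidModeError(LeafAgreeError, ValueError):
    """Annotation mode outside {tool, spreadsheet}."""


class InvalidMethodError(LeafAgreeError, ValueError):
    """Unknown consensus method."""


class InfeasibleAssignmentError(LeafAgreeError, ValueError):
    """An assignment cannot be satisfied (pool too small, K > pool size)."""


class NoOverlapError(LeafAgreeError, ValueError):
    """Two count sources share no image after filtering."""


class InsufficientDataError(LeafAgreeError, ValueError):
    """Not enough data for the requested statistic."""


class MissingDataError(LeafAgreeError, ValueError):
    """Required images have no counts.

    Attributes
    ----------
    image_ids : list of str
        The offending image identifiers.
    """

    def __init__(self, message, image_ids=None):
        super().__init__(message)
        self.image_ids = list(image_ids) if image_ids is not None else []


class ModelError(LeafAgreeError, ValueError):
    """Model could not be fit (rank deficiency, no convergence)."""


class ShapeError(LeafAgreeError, ValueError):
    """Array dimensions do not line up."""


class ParseError(LeafAgreeError, ValueError):
    """A file could not be parsed.

    Attributes
    ----------
    row : int or None
        1-based data row number (excluding the header) when known.
    column : str or None
        Offending column name when known.
    """

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column
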