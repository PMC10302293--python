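"""Exception types shared across the package."""


class CherrypopError(Exception):
    """Base class for package errors."""


class AlignmentError(CherrypopError):
    """Malformed alignment (ragged rows, empty matrix, all-gap row)."""


class InputError(CherrypopError):
    """Invalid or inconsistent user input (metadata, labels, config)."""


class InsufficientDataError(CherrypopError):
    """A statistic was requested on a subset too small to define it."""


class ScenarioError(CherrypopError):
    """Invalid demographic scenario (e.g. demes that never share an ancestor)."""


class ConvergenceError(CherrypopError):
    """An iterative algorithm failed to converge within its iteration budget."""
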