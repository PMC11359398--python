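"""Exception types shared across the package."""


class HistotexError(Exception):
    """Base class for errors raised by histotex."""


class DegenerateInputError(HistotexError, ValueError):
    """Input is structurally valid but degenerate for the requested operation.

    Examples: a constant-intensity histogram passed to Otsu thresholding, a
    patch too small for every configured co-occurrence offset, a feature
    table with fewer than two rows passed to standardization.
    """


class ConfigurationError(HistotexError, ValueError):
    """A configuration value is inconsistent (e.g. a label without a palette
    entry, mismatched feature dimensions)."""


class NumericalError(HistotexError, ArithmeticError):
    """A numerical failure with a diagnostic message (e.g. coincident
    cluster centroids with positive scatter, a singular covariance that
    regularization could not repair)."""
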