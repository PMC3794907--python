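"""Exception hierarchy."""


class PathratesError(Exception):
    """Base class for all errors raised by this package."""


class TreeError(PathratesError):
    """Invalid phylogeny: malformed Newick, missing branch lengths,
    non-ultrametric tree, or a tip set that is not a clade."""


class DataError(PathratesError):
    """Invalid expression matrix, contrast matrix, or gene-set input."""


class FitError(PathratesError):
    """Model fitting failed or was attempted on degenerate data."""
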