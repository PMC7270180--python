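"""Exception hierarchy.

Every anticipated failure mode raises a distinct subclass of
:class:`TilscopeError` so callers (and the CLI) can tell configuration
problems, malformed inputs, and degenerate data apart.
"""


class TilscopeError(Exception):
    """Base class for all package errors."""


class MissingComponentError(TilscopeError):
    """A required file of an expression triplet directory is absent."""


class InconsistentTripletError(TilscopeError):
    """Matrix header dimensions disagree with barcode/feature table lengths."""


class SchemaError(TilscopeError):
    """A mandatory column is missing from a tabular input."""


class EmptyAfterQcError(TilscopeError):
    """Quality-control filtering removed every cell."""


class NoReferenceGenesError(TilscopeError):
    """No gene in the top-ranked panel has a positive geometric mean.

    Raised by ranked-GLSF normalization; advise a smaller panel
    (``top_n_rank``) or the pseudocount mode.
    """


class EmptyGeneModelError(TilscopeError):
    """Coverage/dispersion gene-model selection returned no genes."""


class NoClusterStructureError(TilscopeError):
    """All embedded points are identical; clustering is undefined."""


class ConfigError(TilscopeError):
    """Invalid or inconsistent configuration value."""
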