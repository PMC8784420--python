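"""Exception hierarchy.

Every error the pipeline can raise deliberately derives from
:class:`IrlncError`, so the CLI can map validation failures to a single
exit code while programming errors propagate unchanged.
"""


class IrlncError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IrlncError):
    """An input file violates its documented format or an invariant."""


class EmptySplitError(IrlncError):
    """Biotype split produced zero mRNAs or zero lncRNAs."""


class UndefinedCorrelationError(IrlncError):
    """Correlation requested for a zero-variance (or too-short) vector."""


class UndefinedPartialError(IrlncError):
    """Partial correlation undefined because a conditioning correlation is ±1."""


class InsufficientSamplesError(IrlncError):
    """Fewer shared samples than the minimum required for the statistic."""


class InsufficientGroupError(IrlncError):
    """A tumor or normal group has too few samples for differential expression."""


class NoOverlapError(IrlncError):
    """A gene set shares no genes with a ranked list."""


class ConfigurationError(IrlncError):
    """A parameter value is outside its valid range."""
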