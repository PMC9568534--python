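"""Exception hierarchy shared across the package."""


class HlcBenchError(Exception):
    """Base class for all package errors."""


class FormatError(HlcBenchError):
    """Malformed external file (counts, metadata, GMT, tables)."""


class MergeError(HlcBenchError):
    """Cross-study matrices cannot be combined."""


class ValidationError(HlcBenchError):
    """A precondition on in-memory inputs is violated."""


class FitError(HlcBenchError):
    """A model fit cannot proceed (too few usable genes, degenerate data)."""
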