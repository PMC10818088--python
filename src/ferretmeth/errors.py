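"""Exception hierarchy shared across the package."""


class FerretMethError(Exception):
    """Base class for package errors."""


class FormatError(FerretMethError, ValueError):
    """A file does not conform to its declared dialect."""


class InvalidConfigError(FerretMethError, ValueError):
    """A configuration object violates its invariants."""


class PipelineError(FerretMethError, RuntimeError):
    """A pipeline stage failed at run time."""
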