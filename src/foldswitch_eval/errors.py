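"""Exception hierarchy.

Everything raised on bad user input derives from :class:`FoldswitchEvalError`
so the CLI can map validation failures to exit code 2.
"""


class FoldswitchEvalError(Exception):
    """Base class for all package-level errors."""


class FormatError(FoldswitchEvalError):
    """A file does not conform to its declared format."""


class ParameterError(FoldswitchEvalError):
    """A parameter value violates a precondition."""


class ValidationError(FoldswitchEvalError):
    """A domain-object invariant or configuration contract is violated."""
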