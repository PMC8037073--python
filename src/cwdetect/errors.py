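"""Exception hierarchy.

Validation/parameter problems (bad user input) are distinguished from contract
violations (library misuse, e.g. asking for marginals of a truncated
distribution) so the CLI can map them to distinct exit codes.
"""


class CwdetectError(Exception):
    """Base class for all package errors."""


class ValidationError(CwdetectError):
    """Input data violates a documented invariant (ragged leads, short record...)."""


class ParameterError(CwdetectError):
    """A parameter is outside its documented domain."""


class FormatError(CwdetectError):
    """A file could not be interpreted in the declared format."""


class ContractError(CwdetectError):
    """An operation was called in a state its contract forbids."""
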