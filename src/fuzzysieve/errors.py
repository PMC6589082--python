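"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`FuzzysieveError`, so callers (and the CLI) can distinguish user
errors from bugs.
"""


class FuzzysieveError(Exception):
    """Base class for all errors raised by fuzzysieve."""


class TemplateError(FuzzysieveError):
    """Malformed template file, pattern token, or list file."""


class VariableError(FuzzysieveError):
    """Unknown variable reference, missing field, or rebinding."""


class InputError(FuzzysieveError):
    """Problem with the input read files (ragged tail, unpaired files, ...)."""


class MatchError(FuzzysieveError):
    """Internal inconsistency detected while matching a record."""
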