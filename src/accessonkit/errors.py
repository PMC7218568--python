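"""Exception hierarchy shared across the toolkit."""


class AccessonKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AccessonKitError):
    """An input file is malformed or inconsistent with its sidecar files."""


class ValidationError(AccessonKitError):
    """Input values violate a documented invariant (e.g. negative counts)."""


class ConfigurationError(AccessonKitError):
    """A requested operation needs data or parameters that were not supplied."""


class ParameterError(AccessonKitError):
    """A parameter is outside its valid range."""


class EmptyResultError(AccessonKitError):
    """A filter or search removed everything; the message reports the counts."""
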