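"""Exception hierarchy shared across the package.

Every error raised on a user-facing path derives from :class:`SvrecError`
so the command-line layer can map them to a single non-zero exit code.
"""


class SvrecError(Exception):
    """Base class for all svrec errors."""


class InputError(SvrecError):
    """A required input file is missing or unreadable."""


class FormatError(SvrecError):
    """An input file violates its format contract (names the offending record)."""


class ValidationError(SvrecError):
    """A value violates a documented precondition or invariant."""


class EmptyInputError(SvrecError):
    """An operation that needs at least one record received none."""


class ModelLoadError(SvrecError):
    """A persisted model could not be loaded (corrupt or wrong format version)."""


class ConfigError(SvrecError):
    """A simulation or run configuration is internally inconsistent."""
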