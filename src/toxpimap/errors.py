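"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes: validation problems exit 2,
file/format problems exit 3, statistical preconditions exit 4.
"""


class ToxpimapError(Exception):
    """Base class for all package errors."""


class ValidationError(ToxpimapError):
    """Invalid model, table, or parameter content."""


class DataIOError(ToxpimapError):
    """Unreadable/unwritable file or unsupported format."""


class StatisticalError(ToxpimapError):
    """A statistical precondition is violated (e.g. zero variance)."""
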