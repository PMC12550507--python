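"""Exception hierarchy shared across the package.

Schema problems (a column missing, an unknown file layout) are distinguished
from validation problems (a row with lat > 90, a duplicate id) so the CLI can
map both onto exit code 2 while library users can catch them separately.
"""


class EcometricaError(Exception):
    """Base class for all package errors."""


class SchemaError(EcometricaError):
    """The input file does not have the expected columns or structure."""


class ValidationError(EcometricaError):
    """The input parses but violates an invariant (bad coordinates, duplicates)."""


class ArchiveError(EcometricaError):
    """A model archive is unreadable, corrupted, or of an unknown version."""
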