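"""Exception hierarchy shared across the pipeline."""


class SuiCuaError(Exception):
    """Base class for all package errors."""


class ValidationError(SuiCuaError, ValueError):
    """Input data violates an instrument or type invariant."""


class ConfigError(SuiCuaError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class ParticipantDataError(ValidationError):
    """Aggregated row-level validation failures for a participant CSV.

    Parameters
    ----------
    errors
        List of ``(row_number, message)`` pairs; row numbers are 1-based
        positions in the file including the header.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "\n".join(f"  row {row}: {msg}" for row, msg in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s):\n{lines}")
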