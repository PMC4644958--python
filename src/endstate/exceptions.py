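"""Exception hierarchy for endstate.

Every error raised by the package derives from :class:`EndstateError`, so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class EndstateError(Exception):
    """Base class for all endstate errors."""


class PDBParseError(EndstateError):
    """A PDB/XYZ record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(EndstateError):
    """Frames/models are structurally inconsistent (atom counts, ordering)."""


class ParameterizationError(EndstateError):
    """Atoms are missing force-field parameters required for an operation."""


class SelectionError(EndstateError):
    """Selection expression failed to parse; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"at position {position}: {message}"
        super().__init__(message)


class ConfigurationError(EndstateError):
    """Analysis was configured inconsistently with its inputs."""


class SingularityError(EndstateError):
    """Two interacting atoms (near-)coincide, making pair energies undefined."""


class ConvergenceError(EndstateError):
    """An iterative solver failed to reach its tolerance."""
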