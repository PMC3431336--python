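"""Exception types shared across the package."""


class TriregError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TriregError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(TriregError, ValueError):
    """A configuration object is internally inconsistent."""


class ParseError(TriregError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class RoleError(TriregError, ValueError):
    """A gene carries a role incompatible with the requested operation."""


class UndefinedScoreError(TriregError, ValueError):
    """Similarity score is undefined (max and min attainable sums coincide)."""


class StageError(TriregError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
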