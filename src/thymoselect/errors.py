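"""Exception hierarchy shared across the package."""


class ThymoselectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ThymoselectError):
    """An input file does not conform to the expected dialect."""


class ConfigurationError(ThymoselectError):
    """Missing or inconsistent run configuration (metadata, gene names, ...)."""


class InputError(ThymoselectError):
    """Arguments violate an operation's preconditions."""


class CoverageUnreachableError(InputError):
    """Requested coverage level cannot be reached within the extrapolation range."""

    def __init__(self, label: str, level: float, max_coverage: float):
        self.label = label
        self.level = level
        self.max_coverage = max_coverage
        super().__init__(
            f"coverage level {level} unreachable for {label!r}: "
            f"maximum attainable within range is {max_coverage:.6f}"
        )
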