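"""Exception hierarchy shared across the package."""


class StackBoxError(Exception):
    """Base class for all package-specific errors."""


class InvalidBoxError(StackBoxError, ValueError):
    """A bounding box violates its geometric invariants."""


class ValidationError(StackBoxError, ValueError):
    """An input record fails a contract check (score range, missing key...)."""


class ConfigurationError(StackBoxError, ValueError):
    """Inconsistent configuration (roster mismatch, unknown backend...)."""


class TrainingError(StackBoxError, RuntimeError):
    """The meta-learner cannot be fitted (e.g. empty match table)."""


class GenerationError(StackBoxError, RuntimeError):
    """The synthetic-scenario generator cannot satisfy its constraints."""
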