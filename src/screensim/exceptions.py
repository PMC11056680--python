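"""Exception hierarchy for screensim."""


class ScreensimError(Exception):
    """Base class for all screensim errors."""


class ParameterError(ScreensimError, ValueError):
    """An input parameter violates its constraints."""


class EmptyInputError(ScreensimError, ValueError):
    """An operation received an empty collection where data is required."""


class ConfigurationError(ScreensimError, ValueError):
    """Arm / run configuration is inconsistent or incomplete."""


class SchemaError(ScreensimError, ValueError):
    """A CSV or config file does not match the expected schema."""


class UndefinedResultError(ScreensimError, ZeroDivisionError):
    """A ratio (precision, ICER) is undefined for the given inputs."""


class BracketingError(ScreensimError, ValueError):
    """Root finding failed because the bracket does not change sign."""
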