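"""Exception hierarchy shared across the package."""


class QSARLabError(Exception):
    """Base class for all qsarlab errors."""


class SpecificationError(QSARLabError, ValueError):
    """An input specification (synthetic spec, config) is inconsistent."""


class ConfigError(QSARLabError, ValueError):
    """An algorithm configuration value is out of range."""


class DegenerateInputError(QSARLabError, ValueError):
    """An input makes the requested quantity mathematically undefined."""


class CollinearityError(QSARLabError, ValueError):
    """A design matrix is rank deficient.

    ``columns`` names the offending (linearly dependent) columns when they
    could be identified.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(QSARLabError, ValueError):
    """Too few rows for the requested fit or statistic."""


class LeakageError(QSARLabError, ValueError):
    """Training and evaluation sets share compounds."""


class MissingDescriptorError(QSARLabError, KeyError):
    """A model requires descriptor columns absent from the supplied table."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing descriptor columns: {', '.join(self.missing)}")


class UnknownTemplateError(QSARLabError, KeyError):
    """Requested toy-molecule template or published equation does not exist."""
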