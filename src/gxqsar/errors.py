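"""Exception hierarchy shared across the package."""


class GxQsarError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(GxQsarError, ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


class VocabularyError(GxQsarError, KeyError):
    """An unregistered descriptor or atom-type label was requested."""

    def __init__(self, name, known):
        self.name = name
        self.known = sorted(known)
        super().__init__(
            f"unknown name {name!r}; registered names: {', '.join(self.known)}"
        )


class SingularMatrixError(GxQsarError, ValueError):
    """Design matrix is rank deficient (collinear descriptor columns)."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design matrix; collinear columns: {self.columns}")


class DegreesOfFreedomError(GxQsarError, ValueError):
    """Too few observations for the number of fitted parameters."""


class MissingDescriptorError(GxQsarError, KeyError):
    """A model was asked to predict from a vector lacking a required descriptor."""

    def __init__(self, names):
        self.names = list(names)
        super().__init__(f"descriptor vector is missing required value(s): {self.names}")


class InfluentialPointError(GxQsarError, ValueError):
    """A leverage of 1 makes the leave-one-out residual undefined."""


class UndefinedStatisticError(GxQsarError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ConfigError(GxQsarError, ValueError):
    """Invalid simulation or screening configuration."""
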