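"""Exception hierarchy shared across the package."""


class EconoChoiceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EconoChoiceError):
    """A file's structure (columns, header, row shape) is wrong."""


class ValidationError(EconoChoiceError):
    """A file parsed structurally but a value violates the data model."""


class PairingError(EconoChoiceError):
    """Sessions cannot be matched into blocked/patent pairs."""


class DesignError(EconoChoiceError):
    """An ANOVA layout is unbalanced or singular."""


class ParameterError(EconoChoiceError):
    """A simulation or analysis parameter is outside its allowed range."""


class InputError(EconoChoiceError):
    """Inputs to a fit or statistic are unusable (e.g. zero trials)."""
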