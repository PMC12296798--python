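"""Exception hierarchy for survweight."""


class SurvweightError(Exception):
    """Base class for all survweight errors."""


class InvalidDataset(SurvweightError):
    """Dataset violates the structural requirements of the estimators."""


class NonConvergence(SurvweightError):
    """Newton iteration failed to converge (e.g. monotone likelihood)."""


class SingularInformation(SurvweightError):
    """Observed information matrix is singular (collinear covariates)."""


class SingularDispersion(SurvweightError):
    """Covariate dispersion matrix of the additive model is singular."""


class MissingColumn(SurvweightError):
    """A column named in the run configuration is absent from the input."""


class UnparseableValue(SurvweightError):
    """A cell could not be interpreted (row and column are reported)."""


class EmptyAfterFiltering(SurvweightError):
    """No usable rows remain after dropping incomplete records."""
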