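"""Exception hierarchy shared across the package."""


class AlbisoilError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(AlbisoilError):
    """A table failed structural validation (missing cells, bad shapes...)."""


class DesignError(AlbisoilError):
    """A sample refers to a treatment absent from the experimental design."""


class ParameterError(AlbisoilError):
    """An invalid parameter value (negative CV, targets summing >= 1...)."""


class DegenerateDataError(AlbisoilError):
    """Data degenerate for the requested statistic (constant column, xmin == xmax...)."""
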