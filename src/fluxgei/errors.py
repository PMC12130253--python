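"""Exception hierarchy shared across the package."""


class FluxGEIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FluxGEIError):
    """Invalid simulation or pipeline configuration (non-PSD matrix, bad MAF, ...)."""


class ValidationError(FluxGEIError):
    """Input data violates a documented contract (out-of-range values, schema)."""


class DegenerateDesignError(FluxGEIError):
    """A design matrix carries no information for some coefficient
    (constant column within every stratum, monomorphic dosage, ...)."""


class FitError(FluxGEIError):
    """A model fit could not be carried out (zero events, singular information)."""
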