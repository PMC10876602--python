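"""Exception hierarchy for the ofsca package."""


class OfscaError(Exception):
    """Base class for all ofsca errors."""


class ConfigError(OfscaError, ValueError):
    """Invalid analysis configuration (scales, orders, fit windows...)."""


class FitError(OfscaError, RuntimeError):
    """A scaling-exponent fit could not be performed."""


class SingularMixingError(OfscaError, ValueError):
    """Mixing/demixing matrix is (near-)singular for the given angle pair."""


class SchemaError(OfscaError, ValueError):
    """An input table does not have the expected columns/layout."""
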