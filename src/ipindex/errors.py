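"""Exception types shared across the package."""


class IPIndexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IPIndexError, ValueError):
    """A calibration config, partition, or rule base is structurally invalid."""


class InvalidSampleError(IPIndexError, ValueError):
    """A crisp input value cannot be fuzzified (e.g. NaN/inf)."""


class NoRuleFiredError(IPIndexError, RuntimeError):
    """Defuzzification was requested with all consequent activations zero."""


class UndefinedMetricError(IPIndexError, ArithmeticError):
    """Sensitivity/specificity requested with a zero denominator."""


class VitalsFormatError(IPIndexError, ValueError):
    """A vitals CSV file does not match the expected dialect."""


class ScenarioError(IPIndexError, ValueError):
    """A synthetic scenario specification is invalid (e.g. overlapping episodes)."""
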