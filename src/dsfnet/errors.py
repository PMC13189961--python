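"""Shared exception types."""


class ConfigurationError(ValueError):
    """A requested configuration is invalid or infeasible."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
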