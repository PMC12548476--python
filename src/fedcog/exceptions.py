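"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericError -> 4.
"""


class FedcogError(Exception):
    """Base class for all package errors."""


class ConfigError(FedcogError):
    """Invalid configuration (bad fractions, unknown scenario or method, ...)."""


class DataError(FedcogError):
    """Invalid or infeasible data (exhausted class pool, empty table, bad CSV, ...)."""


class NumericError(FedcogError):
    """Numerical failure during training or aggregation (non-finite values)."""
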