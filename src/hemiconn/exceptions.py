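"""Exception hierarchy shared across the pipeline."""


class HemiconnError(Exception):
    """Base class for all package-specific errors."""


class SchemeError(HemiconnError, ValueError):
    """Invalid node scheme (montage/parcellation) definition."""


class DataError(HemiconnError, ValueError):
    """Invalid input data (shape, finiteness, variance, length)."""


class ConfigError(HemiconnError, ValueError):
    """Invalid configuration or parameters."""


class RewireError(HemiconnError, ValueError):
    """Network randomization cannot proceed (too few nodes/edges)."""


class StatsError(HemiconnError, ValueError):
    """Degenerate input to a statistical routine."""
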