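"""Exception hierarchy for nervestereo."""


class NerveStereoError(Exception):
    """Base class for all nervestereo errors."""


class DistributionError(NerveStereoError):
    """Invalid or infeasible parametric distribution specification."""


class PackingError(NerveStereoError):
    """Fiber population cannot be packed into the nerve cross-section."""


class RenderError(NerveStereoError):
    """Raster rendering would exceed the configured pixel budget."""


class DesignError(NerveStereoError):
    """Invalid sampling design or frame geometry."""


class MeasureError(NerveStereoError):
    """Invalid morphometric input (non-positive or inverted areas)."""


class EstimateError(NerveStereoError):
    """Invalid input to a density / total-number estimator."""


class StatsError(NerveStereoError):
    """Invalid input to a statistical comparison."""


class ConfigError(NerveStereoError):
    """Invalid pipeline configuration."""


class ParseError(NerveStereoError):
    """Malformed tabular input file."""
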