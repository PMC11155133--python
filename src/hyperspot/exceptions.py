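"""Exception hierarchy used across the package."""


class HyperspotError(Exception):
    """Base class for all package-specific errors."""


class DataError(HyperspotError, ValueError):
    """Malformed or inconsistent input data."""


class NoSpatialInformationError(DataError):
    """Input carries no spatial coordinates."""


class AlignmentError(DataError):
    """Expression matrix and coordinate/label table disagree in length or order."""


class EmptyGeneSetError(DataError):
    """A filtering step removed every gene."""


class EmptySpotError(DataError):
    """A spot has zero total counts and cannot be normalized."""


class GraphError(HyperspotError, ValueError):
    """Invalid hypergraph or neighbor-graph construction."""


class TooFewSpotsError(GraphError):
    """Fewer spots than the requested neighborhood size allows."""


class DegenerateVertexError(GraphError):
    """A vertex with zero hypergraph degree; normalization undefined."""


class ConfigError(HyperspotError, ValueError):
    """Invalid hyperparameter or model configuration."""


class NumericalError(HyperspotError, RuntimeError):
    """Non-finite values encountered during optimization."""
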