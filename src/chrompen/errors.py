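"""Exception hierarchy.

All package-specific failures derive from :class:`ChromPenError` so callers
(and the CLI) can distinguish data/validation problems (exit code 1) from
usage errors (exit code 2, raised by the argument parser itself).
"""


class ChromPenError(Exception):
    """Base class for all chrompen errors."""


class ParseError(ChromPenError, ValueError):
    """A file could not be parsed; the message names the offending line/row."""


class SchemaError(ChromPenError, ValueError):
    """A tabular/JSON input is missing required fields."""


class ValidationError(ChromPenError, ValueError):
    """A domain invariant is violated (coordinates, weights, ranges...)."""


class FitInfeasibleError(ChromPenError, RuntimeError):
    """Too little usable data to fit the decay model."""


class MetricError(ChromPenError, ValueError):
    """A profile-comparison metric is undefined for the given inputs."""


class SimulationError(ChromPenError, ValueError):
    """A synthetic-data configuration is numerically unusable."""
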