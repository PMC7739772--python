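"""Exception hierarchy shared across the pipeline.

Every validated failure raises one of these so the CLI can distinguish a
usage problem (bad column name, bad config) from bad data (non-positive
cell, constant predictor) and exit with a message rather than a traceback.
"""


class SprintCpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SprintCpError):
    """A column, predictor, or config field could not be resolved."""


class ValidationError(SprintCpError):
    """Input data violate an invariant (non-positive cell, bad lengths...)."""


class DegenerateDataError(SprintCpError):
    """Data are structurally unusable for a fit (constant predictor,
    too few points, rank-deficient design, exhausted resampling)."""
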