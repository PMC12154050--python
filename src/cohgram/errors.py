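"""Exception hierarchy shared by all pipeline stages."""


class CohgramError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CohgramError):
    """A parameter object violates its own invariants."""


class InputError(CohgramError):
    """A file or in-memory input is malformed or inconsistent."""


class EstimationError(CohgramError):
    """A spectral estimate is degenerate (too few Welch sub-segments,
    zero-variance input, ...)."""


class ContractError(CohgramError):
    """An internal data contract was violated (e.g. an asymmetric matrix
    passed where a symmetric one is required)."""
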