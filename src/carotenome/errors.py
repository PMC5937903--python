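"""Exception hierarchy for the carotenome pipeline."""


class CarotenomeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(CarotenomeError, ValueError):
    """Plex design parameters are impossible (non-positive counts, etc.)."""


class InvalidParameterError(CarotenomeError, ValueError):
    """Generator or model parameters are outside their admissible range."""


class UnknownProteinError(CarotenomeError, KeyError):
    """A referenced protein is absent from the abundance matrix."""


class DataIntegrityError(CarotenomeError, ValueError):
    """Input data violate a structural invariant (e.g. non-positive
    concentration that is not flagged below the detection limit)."""


class NoSlopeVarianceError(CarotenomeError, ValueError):
    """The predictor is constant: the slope is not estimable."""


class InsufficientGroupsError(CarotenomeError, ValueError):
    """Fewer than two plexes among the complete cases."""


class InsufficientDataError(CarotenomeError, ValueError):
    """Fewer complete observations than the configured floor; callers treat
    this as a skip-this-protein signal rather than a fatal error."""


class InvalidPValueError(CarotenomeError, ValueError):
    """A p-value outside [0, 1] (or NaN) was passed to the FDR routine."""


class ConfigError(CarotenomeError, ValueError):
    """Pipeline configuration is missing or inconsistent."""
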