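"""Exception hierarchy."""


class CimsymError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CimsymError, ValueError):
    """A parameter violates its documented constraints."""


class InputConsistencyError(CimsymError, ValueError):
    """Inputs reference each other inconsistently (dangling ids, overlaps)."""


class SimulationError(CimsymError, RuntimeError):
    """The synthetic-data generator could not satisfy the requested scenario."""
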