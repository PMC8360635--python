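"""Exception hierarchy for pidnoise."""


class PidNoiseError(Exception):
    """Base class for all pidnoise errors."""


class InvalidParameterError(PidNoiseError, ValueError):
    """A circuit or distribution parameter violates its domain constraints."""


class StabilityError(PidNoiseError, RuntimeError):
    """The linearized moment dynamics matrix is not Hurwitz."""


class DegenerateLinearizationError(PidNoiseError, RuntimeError):
    """A regulating species has zero steady-state mean, so the relative
    deviation used by the linear noise approximation is undefined."""


class NumericalConditioningError(PidNoiseError, RuntimeError):
    """A moment solve produced residuals or negative variances beyond
    tolerance."""


class RunawayPopulationError(PidNoiseError, RuntimeError):
    """A simulated population exceeded the configured cap, which usually
    indicates a mis-parameterized (unstable or near-critical) circuit."""


class NoInteriorMinimumError(PidNoiseError, ValueError):
    """An optimal-gain formula was requested in a regime with no interior
    optimum (e.g. noiseless controller, CV²_Z = 0)."""


class InvalidWindowError(PidNoiseError, ValueError):
    """A statistics window (burn-in, horizon) is empty or inverted."""
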