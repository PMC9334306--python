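"""Exception hierarchy shared across the package."""


class HardcogError(Exception):
    """Base class for all package-specific errors."""


class InvalidInstanceError(HardcogError, ValueError):
    """An instance violates its type invariants."""


class FormatError(HardcogError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ConfigurationError(HardcogError, ValueError):
    """A generator or run configuration is internally inconsistent."""


class GenerationError(HardcogError, RuntimeError):
    """Random generation could not satisfy its post-conditions."""


class UnsupportedSizeError(HardcogError, ValueError):
    """Instance is larger than the exact-solver regime supports."""


class ConsistencyError(HardcogError, ValueError):
    """A solve result was paired with an instance it was not computed from."""


class UnclassifiedAlphaError(HardcogError, ValueError):
    """A constrainedness value falls outside every declared region band."""


class RangeError(HardcogError, ValueError):
    """A satisfiability curve does not bracket the 0.5 crossing."""


class DesignError(HardcogError, RuntimeError):
    """A stratified design cell could not be filled from the candidate pool."""


class DegeneratePoolError(HardcogError, ValueError):
    """A pool is too small for the requested split."""


class SpecificationError(HardcogError, ValueError):
    """A model or effect specification names predictors that do not exist."""


class FitError(HardcogError, RuntimeError):
    """Model fitting failed in a way that cannot be reported as a result."""
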