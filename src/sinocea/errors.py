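"""Exception types shared across the package."""


class SinoceaError(Exception):
    """Base class for all package-specific errors."""


class InvalidLifeTableError(SinoceaError, ValueError):
    """A life table failed validation (non-contiguous ages, q outside [0, 1], ...)."""


class AgeRangeError(SinoceaError, ValueError):
    """An age lookup fell below the tabulated range, or outside a model's horizon."""


class InvalidSpecError(SinoceaError, ValueError):
    """A model specification contains non-finite or out-of-range parameters."""


class InfeasibleMomentsError(SinoceaError, ValueError):
    """A beta distribution cannot be moment-matched (implied variance too large)."""


class NoThresholdInRangeError(SinoceaError, ValueError):
    """A one-way threshold search found no ICER = WTP crossing inside the bounds."""


class NoCrossingError(SinoceaError, ValueError):
    """An age-threshold scan found the strategy cost-effective at no age or all ages.

    The ``direction`` attribute is ``"all"`` or ``"none"``.
    """

    def __init__(self, message: str, direction: str):
        super().__init__(message)
        self.direction = direction
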