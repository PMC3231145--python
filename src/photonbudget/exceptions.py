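"""Exception hierarchy for photonbudget."""


class PhotonBudgetError(Exception):
    """Base class for all photonbudget errors."""


class InvalidParameterError(PhotonBudgetError, ValueError):
    """A numeric argument violates its physical domain (sign, range)."""


class ConfigurationError(PhotonBudgetError, ValueError):
    """An optical-train or system configuration is inconsistent.

    Carries an aggregated list of human-readable violation messages in
    ``violations`` so a caller can report every problem at once.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations if violations is not None else [message]


class NoRealImageError(InvalidParameterError):
    """Thin-lens conjugate has no real solution (object at or inside focus)."""


class ResolutionError(InvalidParameterError):
    """A numerical discretisation is too coarse for a reliable result."""


class UnattainableError(PhotonBudgetError):
    """A requested threshold crossing does not occur in the search domain.

    ``asymptote`` holds the limiting signal value (volts) where relevant,
    so callers can report how far from the threshold the system tops out.
    """

    def __init__(self, message: str, asymptote: float | None = None):
        super().__init__(message)
        self.asymptote = asymptote
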