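"""Exception hierarchy for the fishrisk package."""


class FishRiskError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FishRiskError, ValueError):
    """An input violates a mathematical precondition (e.g. negative mass)."""


class MissingReferenceError(FishRiskError, LookupError):
    """A required toxicological reference value is absent for a metal.

    Raised instead of silently defaulting: a THQ without an RfD or a CR
    without a CSF is meaningless, not zero.
    """

    def __init__(self, metal: str, metric: str):
        self.metal = metal
        self.metric = metric
        super().__init__(f"no {metric} available for metal {metal!r}")


class IncompleteProfileError(FishRiskError, ValueError):
    """A tissue profile is missing one or more of the seven metals."""


class ConfigError(FishRiskError, ValueError):
    """Invalid generator or run configuration."""


class DatasetValidationError(FishRiskError, ValueError):
    """A concentration dataset violates its invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "dataset failed validation:\n" + "\n".join(f"  - {v}" for v in violations)
        )
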