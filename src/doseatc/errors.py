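"""Exception hierarchy for the doseatc pipeline."""


class DoseAtcError(Exception):
    """Base class for all doseatc errors."""


class InvalidRecordError(DoseAtcError):
    """A dispense record violates a structural invariant (empty drug name, ...)."""


class InvalidQuantityError(DoseAtcError):
    """A pill quantity is zero or negative where a positive dose is required."""


class InvalidCodeError(DoseAtcError):
    """Text does not parse as a second-level ATC code."""

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"not a valid second-level ATC code: {text!r}")


class UnknownPromptVersionError(DoseAtcError):
    """Prompt version name is not one of the bundled versions."""


class DuplicateInputError(DoseAtcError):
    """A classification batch was built from non-distinct dose strings."""


class ConfigurationError(DoseAtcError):
    """A backend is missing credentials or other required configuration."""


class SamplingError(DoseAtcError):
    """Requested sample size exceeds the eligible population."""


class JoinError(DoseAtcError):
    """Paired grade records do not share the same item set."""

    def __init__(self, missing_left, missing_right):
        self.missing_left = sorted(missing_left)
        self.missing_right = sorted(missing_right)
        super().__init__(
            "grade records do not join: "
            f"only in LLM arm {self.missing_left!r}, only in search arm {self.missing_right!r}"
        )


class GradingError(DoseAtcError):
    """An acceptability mapping is missing an entry for a winner code."""
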