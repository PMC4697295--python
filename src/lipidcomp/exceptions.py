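"""Exception hierarchy for lipidcomp.

All validation problems raise :class:`ValidationError` (a ``ValueError``)
so that callers and the CLI can map any bad-input condition to a single
exit path while still catching more specific subclasses.
"""


class ValidationError(ValueError):
    """Input data or parameters violate a documented precondition."""


class DegenerateInputError(ValidationError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class UnknownFattyAcidError(ValidationError, KeyError):
    """A fatty-acid name is not present in the matrix."""

    def __init__(self, name: str, valid: list[str]):
        self.name = name
        self.valid = list(valid)
        super().__init__(
            f"unknown fatty acid {name!r}; valid names: {', '.join(self.valid)}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class DegenerateBoundaryError(ValidationError):
    """The sign boundary degenerates (e.g. rho1 = 0, or a vertical line)."""
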