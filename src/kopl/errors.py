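"""Exception hierarchy shared across the package."""


class KoplError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(KoplError):
    """Library design violates an invariant (empty alphabet, duplicate entries, ...)."""


class UnknownSetError(KoplError):
    """A set definition does not belong to the given library design."""


class IncompleteMassTableError(KoplError):
    """A residue in the design has no entry in the mass table."""


class UnscoreableSequenceError(KoplError):
    """A 7-mer cannot be scored: wrong central residue or a flank outside the alphabet."""


class SchemaError(KoplError):
    """A tabular input violates the expected schema."""


class CompletenessError(KoplError):
    """A screen is missing measurements for one or more library sets."""

    def __init__(self, missing_set_ids):
        self.missing_set_ids = list(missing_set_ids)
        super().__init__(
            f"screen is missing {len(self.missing_set_ids)} set(s): "
            + ", ".join(self.missing_set_ids)
        )


class ReferenceMismatchError(KoplError):
    """The residue observed at a mutation position differs from the declared reference."""

    def __init__(self, position, expected, observed):
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch at position {position}: expected {expected!r}, "
            f"observed {observed!r}"
        )


class MutationParseError(KoplError):
    """One or more mutation rows could not be parsed; carries per-row messages."""

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        super().__init__("; ".join(self.row_errors))


class FitError(KoplError):
    """Raised when no kinetic model could be fit at all."""


class GenerationError(KoplError):
    """The synthetic-data generator cannot satisfy a request."""
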