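"""Exception hierarchy for RIT assay analysis."""


class RitfitError(Exception):
    """Base class for all ritfit errors."""


class FormatError(RitfitError):
    """Input table is structurally malformed (e.g. a required column is missing)."""


class ParseError(RitfitError):
    """A cell could not be parsed as the required type; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class ValidationError(RitfitError):
    """An assay violates a data invariant (monotonicity, bounds, time-zero rule)."""


class DegenerateFitError(RitfitError):
    """The decay rate is not identifiable from the data (e.g. no decay observed)."""


class InitializationError(RitfitError):
    """Log-linear starting values cannot be computed (too few positive counts)."""


class HalfLifeUndefinedError(RitfitError):
    """The fitted curve never crosses half the initial count, or the rate is zero."""


class BootstrapUnstableError(RitfitError):
    """Too large a fraction of bootstrap refits failed to converge."""


class InsufficientReplicationError(RitfitError):
    """A statistical comparison needs at least two replicates per group."""


class UsageError(RitfitError):
    """The caller combined inputs incorrectly (mixed genotypes, missing reference, ...)."""
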