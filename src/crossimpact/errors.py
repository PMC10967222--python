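"""Exception hierarchy for cross-impact analysis.

Every error raised by the package derives from :class:`CrossImpactError`
so callers (notably the CLI) can catch one type and report a diagnostic.
"""

from __future__ import annotations


class CrossImpactError(Exception):
    """Base class for all package errors."""


class ValidationError(CrossImpactError):
    """A value violates the scoring instrument or a type invariant."""


class LookupError_(CrossImpactError):
    """A goal identifier is not part of the goal set."""


class IncompleteMatrixError(CrossImpactError):
    """Some ordered goal pairs have no final score.

    Attributes
    ----------
    missing : list of (source, target) pairs with no score.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        pairs = ", ".join(f"{s}->{t}" for s, t in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"missing final scores for {len(self.missing)} pair(s): {pairs}{more}")


class ConflictError(CrossImpactError):
    """Two final records for the same ordered pair disagree."""


class CoverageError(CrossImpactError):
    """Two scoring stages do not cover the same set of ordered pairs."""


class UnresolvedTieError(CrossImpactError):
    """A vote ended in an exact plurality tie; escalate to plenary consensus."""

    def __init__(self, pair, tied_scores):
        self.pair = pair
        self.tied_scores = sorted(tied_scores)
        super().__init__(
            f"vote on {pair[0]}->{pair[1]} tied between scores {self.tied_scores}"
        )


class UnresolvedDiscrepancyError(CrossImpactError):
    """Discrepancies remain unresolved when final scores were requested."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        names = ", ".join(f"{s}->{t}" for s, t in self.pairs[:10])
        super().__init__(f"{len(self.pairs)} unresolved discrepancy(ies): {names}")


class FormatError(CrossImpactError):
    """A file does not conform to the expected CSV layout."""


class ParseError(CrossImpactError):
    """A row of an input file failed validation; names the offending row."""

    def __init__(self, message, row=None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class ConfigurationError(CrossImpactError):
    """A generator or analysis configuration is internally inconsistent."""
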