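"""Exception hierarchy for refstab.

Every error raised on bad scientific input derives from :class:`RefstabError`
so callers (and the CLI) can catch domain failures without masking bugs.
"""


class RefstabError(Exception):
    """Base class for all refstab domain errors."""


class InvalidSequenceError(RefstabError):
    """A primer sequence is empty or contains non-ACGT characters."""


class UnknownSpeciesError(RefstabError, KeyError):
    """A species was requested that the assay screen does not contain."""


class InsufficientReplicatesError(RefstabError):
    """Fewer than two replicate Ct values are present in a well set."""


class EmptyTableError(RefstabError):
    """A QC or exclusion step removed every gene (or sample) from a table."""


class CtParseError(RefstabError):
    """A Ct input file violates the documented schema.

    Carries the 1-based data row number where the problem was found.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class InvalidCtError(RefstabError):
    """A Ct value is non-positive or otherwise unusable."""


class DegenerateSeriesError(RefstabError):
    """A dilution series produced a non-negative slope (no amplification trend)."""


class InsufficientPointsError(RefstabError):
    """A dilution series has fewer than three distinct concentrations."""


class TooFewGenesError(RefstabError):
    """A stability analysis needs more candidate genes than were supplied."""


class UndefinedGeneError(RefstabError):
    """A gene has no detected Ct in any sample (should be excluded upstream)."""


class InsufficientGroupError(RefstabError):
    """A sample group is too small for the group-aware stability model."""


class InsufficientGenesError(RefstabError):
    """Fewer than two rankable genes remain after exclusions."""


class EmptyGroupError(RefstabError):
    """A group passed to a statistical test has no usable values."""


class UndefinedFoldError(RefstabError):
    """The control-group summary is zero, so a fold change is undefined."""
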