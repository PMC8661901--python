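"""Exception hierarchy.

Every user-facing failure mode raises a distinct, named error so that callers
(and the CLI) can report which stage of the pipeline rejected the input.
"""


class BseqlabError(Exception):
    """Base class for all package errors."""


# -- metadata ---------------------------------------------------------------

class UnknownProjectError(BseqlabError):
    """The requested project identifier is not present in the master file."""


class MissingMetadataFileError(BseqlabError):
    """A metadata file referenced by the master record does not exist."""


class MetadataParseError(BseqlabError):
    """A metadata field could not be parsed (e.g. a malformed date-time)."""


# -- ingest -----------------------------------------------------------------

class UnknownLabelError(BseqlabError):
    """An event carries a label outside the canonical 45-label vocabulary."""


class OverlappingEventsError(BseqlabError):
    """Two behavior events overlap in time."""


class EmptyInputError(BseqlabError):
    """An input file or collection contains no usable rows."""


class ScheduleError(BseqlabError):
    """The lab light schedule is degenerate or does not cover the recording."""


class ConsistencyRangeError(BseqlabError):
    """Two minute tables share no minutes and cannot be compared."""


# -- categories / features --------------------------------------------------

class UnmappedColumnError(BseqlabError):
    """A behavior column is not covered by the pooling scheme."""


class WindowCoverageError(BseqlabError):
    """A requested time window is not covered by every animal's data."""


class AllRowsExcludedError(BseqlabError):
    """Applying the metadata exclusions removed every animal."""


# -- statistics / machine learning ------------------------------------------

class GroupCountError(BseqlabError):
    """The number of experimental groups is outside the supported 2-3 range."""


class GroupSizeError(BseqlabError):
    """A group is too small for the requested validation scheme."""


class StageError(BseqlabError):
    """Wrapper attaching a pipeline stage name to a propagated error."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
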