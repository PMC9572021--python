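"""Exception hierarchy.

Every error raised on a violated precondition derives from :class:`EegidError`
so callers can distinguish pipeline-contract failures from programming bugs.
"""


class EegidError(ValueError):
    """Base class for all contract violations raised by this package."""


class InvalidCohortError(EegidError):
    """Cohort construction parameters are unusable (e.g. fewer than 2 subjects)."""


class InvalidProfileError(EegidError):
    """A task-load profile violates its invariants (duration, factors, probability)."""


class InvalidProtocolError(EegidError):
    """A session protocol is malformed (duplicate or missing tasks)."""


class InvalidFilterError(EegidError):
    """A filter specification is not realizable at the given sampling rate."""


class InvalidSelectionError(EegidError):
    """A region/channel selection references unknown regions or is empty."""


class CarError(EegidError):
    """Common-average re-referencing requested on fewer than 2 channels."""


class SegmentationError(EegidError):
    """Window/step parameters are non-positive or inconsistent."""


class NormalizationError(EegidError):
    """Normalization fit on empty data or applied with mismatched channels."""


class InvalidConfigError(EegidError):
    """Model or run configuration violates its invariants."""


class DataShapeError(EegidError):
    """Array shapes or label ranges do not match the consuming component."""


class ScenarioError(EegidError):
    """A task-fusion scenario references recordings that are not present."""


class SplitError(EegidError):
    """Train/test or k-fold partitioning parameters are infeasible."""


class ManifestError(EegidError):
    """A cohort manifest is inconsistent (duplicates, missing files)."""


class FormatParseError(EegidError):
    """A signal file could not be parsed; message carries file context."""
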