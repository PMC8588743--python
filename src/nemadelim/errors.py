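"""Exception hierarchy shared across the pipeline stages."""


class NemadelimError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(NemadelimError):
    """Input is not parseable FASTA; message names the offending line."""


class DuplicateRecordError(NemadelimError):
    """Two records share the same (isolate_id, locus) key."""


class AmbiguousPrimerMatchError(NemadelimError):
    """More than one equally good primer match; message lists positions."""


class PrimerOrientationError(NemadelimError):
    """Reverse-primer hit lies upstream of the forward-primer hit."""


class AlignmentError(NemadelimError):
    """Rows of unequal length, missing isolates, or bad partition map."""


class UndefinedComparisonError(NemadelimError):
    """A sequence pair has zero comparable (unambiguous, ungapped) sites."""


class SaturationError(NemadelimError):
    """A model-corrected distance is undefined (logarithm argument <= 0)."""


class MatrixModeError(NemadelimError):
    """Operation requires a similarity- or distance-mode matrix and got the other."""


class GroupingError(NemadelimError):
    """Invalid isolate -> group configuration (empty group, unlabeled isolate)."""


class ReferenceMappingError(NemadelimError):
    """Alignment column cannot be mapped to reference coordinates."""


class MorphometricsError(NemadelimError):
    """Missing characters, bad range table, or unusable identification key."""


class ConfigurationError(NemadelimError):
    """Invalid simulation or pipeline configuration."""
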