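"""Exception hierarchy."""


class PollencorrError(Exception):
    """Base class for package-specific errors."""


class ValidationError(PollencorrError):
    """Input data violates a schema or value constraint."""


class AlignmentError(PollencorrError):
    """Two daily series do not cover compatible date sets."""


class InsufficientOverlapError(AlignmentError):
    """Too few common dates for a meaningful cross-correlation."""


class EmptyCohortError(PollencorrError):
    """A subgroup or cohort operation received no patients."""
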