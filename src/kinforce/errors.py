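"""Exception hierarchy for kinforce."""


class KinforceError(Exception):
    """Base class for all kinforce errors."""


class FormatError(KinforceError, ValueError):
    """Malformed input file (bad column count, bad value, missing header)."""


class NoSharedLociError(KinforceError):
    """A dyad has no usable shared loci after intersection and filtering."""


class EstimatorError(KinforceError):
    """The relatedness estimator cannot be evaluated (e.g. zero denominator)."""
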