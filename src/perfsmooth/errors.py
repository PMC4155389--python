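"""Exception hierarchy for perfsmooth."""


class PerfSmoothError(Exception):
    """Base class for all perfsmooth errors."""


class InvalidParameterError(PerfSmoothError, ValueError):
    """A parameter violates its precondition (non-positive FWHM, empty mask, ...)."""


class DataError(PerfSmoothError, ValueError):
    """Input data is malformed: shape mismatch, non-finite values, bad file."""


class InternalConsistencyError(PerfSmoothError, RuntimeError):
    """An invariant that should be mathematically impossible to break was broken.

    The canonical case is the sum-of-weights denominator underflowing on a mask
    voxel: every mask voxel carries at least its own (positive) kernel centre
    weight, so this can only happen if NaNs propagated into the computation.
    """
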