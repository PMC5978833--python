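"""Exception hierarchy.

``ReachmapError`` is the base for data-level problems (exit code 1 in the
CLI); ``ConfigError`` marks bad configuration (exit code 2).
"""


class ReachmapError(Exception):
    """Base class for data-level errors in the analysis pipeline."""


class InvalidSampleError(ReachmapError):
    """A quaternion sample whose norm deviates from 1 beyond tolerance."""

    def __init__(self, t: float, norm: float, tol: float):
        self.t = t
        self.norm = norm
        super().__init__(
            f"quaternion at t={t:.6g}s has norm {norm:.6g}, "
            f"deviating from 1 by more than {tol:g}"
        )


class InvalidRotationError(ReachmapError):
    """A 3x3 matrix that is not orthonormal with determinant +1."""


class DegenerateDirectionError(ReachmapError):
    """A zero-norm vector used where a direction is required."""


class EmptyStreamError(ReachmapError):
    """An empty sample stream where at least one sample is required."""


class NonMonotoneTimeError(ReachmapError):
    """Timestamps in a stream are not strictly increasing."""


class DegenerateChannelError(ReachmapError):
    """An EMG channel whose RMS envelope is identically zero."""


class TimestampMismatchError(ReachmapError):
    """Pose and EMG series timestamps disagree beyond half a sample interval."""


class ConfigError(Exception):
    """Invalid analysis configuration."""
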