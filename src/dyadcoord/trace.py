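"""Core containers for dyadic movement data.

A :class:`MovementTrace` is one uniformly sampled 1-D displacement series
(e.g. the vertical excursion of an arm curl); a :class:`TrialPair` holds the
aligned participant and avatar traces for one trial together with its
condition labels.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, EmptyInputError, ValidationError

#: tolerance (seconds) on deviations of the time grid from a constant step
TIME_TOL = 1e-6

GAZE_CONDITIONS = ("direct", "averted")
COORDINATION_CONDITIONS = ("spontaneous", "intentional")


@dataclass
class MovementTrace:
    """One uniformly sampled displacement series.

    Parameters
    ----------
    t : array of seconds, strictly increasing with constant step ``1/fs``.
    x : displacement samples (arbitrary units), finite, length >= 2.
    fs : sample rate in Hz.
    trial_id : free-form trial identifier.
    actor : ``"participant"`` or ``"avatar"``.
    """

    t: np.ndarray
    x: np.ndarray
    fs: float
    trial_id: str = ""
    actor: str = "participant"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.x.ndim != 1 or self.t.shape != self.x.shape:
            raise ValidationError("t and x must be 1-D arrays of equal length")
        if len(self.x) < 2:
            raise EmptyInputError("a movement trace needs at least 2 samples")
        if not np.all(np.isfinite(self.x)):
            raise ValidationError("displacement contains non-finite values")
        if self.fs <= 0:
            raise ValidationError("sample rate must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) > TIME_TOL:
            raise ValidationError(
                "time grid deviates from constant step 1/fs by more than "
                f"{TIME_TOL} s; resample first"
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (sample-period convention: n / fs)."""
        return len(self.x) / self.fs

    def with_data(self, t: np.ndarray, x: np.ndarray) -> "MovementTrace":
        """Copy of this trace with new samples but the same metadata."""
        return replace(self, t=np.asarray(t, float), x=np.asarray(x, float))


@dataclass
class TrialPair:
    """Aligned participant + avatar traces for one trial."""

    participant: MovementTrace
    avatar: MovementTrace
    gaze_condition: str = "direct"
    coordination: str = "spontaneous"
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.gaze_condition not in GAZE_CONDITIONS:
            raise ValidationError(
                f"gaze_condition must be one of {GAZE_CONDITIONS}"
            )
        if self.coordination not in COORDINATION_CONDITIONS:
            raise ValidationError(
                f"coordination must be one of {COORDINATION_CONDITIONS}"
            )
        if abs(self.participant.fs - self.avatar.fs) > 1e-9:
            raise AlignmentError("participant and avatar sample rates differ")

    @property
    def fs(self) -> float:
        return self.participant.fs

    @property
    def gaze_code(self) -> int:
        """0 = direct, 1 = averted."""
        return 0 if self.gaze_condition == "direct" else 1

    @property
    def coordination_code(self) -> int:
        """0 = spontaneous, 1 = intentional."""
        return 0 if self.coordination == "spontaneous" else 1
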