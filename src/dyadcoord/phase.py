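"""Relative-phase coordination metrics.

Instantaneous phase comes from the analytic signal (Hilbert transform);
the dyad's relative phase phi is the wrapped difference of the two phase
series. Coordination stability rho is the mean resultant length of the
signed relative-phase distribution: 1 means perfect phase locking, 0 means
no preferred phase relation. rho is Fisher-transformed (atanh) before
linear modelling so the bounded 0-1 scale does not distort inference.

rho is deliberately computed on the *signed* phase wrapped to
(-180, 180]; the folded 0-180 representation is kept for descriptive
distributions only, because folding would count a symmetric {-90, +90}
dispersion as perfect 90-degree locking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import (
    AlignmentError,
    DegenerateSignalError,
    EmptyInputError,
    ValidationError,
)
from .trace import MovementTrace, TrialPair

__all__ = [
    "RelativePhaseSeries",
    "StabilityResult",
    "instantaneous_phase",
    "relative_phase",
    "rho",
    "fisher_z",
    "phase_coordination",
]

#: clip applied before atanh so rho = 1 maps to a finite value
FISHER_EPS = 1e-6


@dataclass
class RelativePhaseSeries:
    """Per-sample relative phase in degrees.

    phi_signed lies in (-180, 180]; phi_folded = |phi_signed| in [0, 180].
    """

    phi_signed: np.ndarray
    phi_folded: np.ndarray

    def __len__(self) -> int:
        return len(self.phi_signed)


@dataclass
class StabilityResult:
    """Coordination stability and its Fisher transformation."""

    rho: float
    rho_z: float


def instantaneous_phase(trace: MovementTrace | np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) of a centred, band-limited signal."""
    x = trace.x if isinstance(trace, MovementTrace) else np.asarray(trace, float)
    if np.max(np.abs(x)) == 0:
        raise DegenerateSignalError("all-zero signal has no phase")
    return np.angle(hilbert(x))


def _wrap_degrees(phi: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to the interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - phi, 360.0)


def relative_phase(p_phase: np.ndarray, a_phase: np.ndarray) -> RelativePhaseSeries:
    """Relative phase (participant minus avatar), both inputs in radians."""
    p_phase = np.asarray(p_phase, float)
    a_phase = np.asarray(a_phase, float)
    if p_phase.shape != a_phase.shape:
        raise AlignmentError(
            f"phase series lengths differ: {p_phase.shape} vs {a_phase.shape}"
        )
    signed = _wrap_degrees(np.degrees(p_phase - a_phase))
    return RelativePhaseSeries(phi_signed=signed, phi_folded=np.abs(signed))


def rho(series: RelativePhaseSeries | np.ndarray) -> float:
    """Mean resultant length of the signed relative-phase distribution.

    Accepts a :class:`RelativePhaseSeries` or an array of signed phase
    values in degrees. Returns a value in [0, 1].
    """
    phi = series.phi_signed if isinstance(series, RelativePhaseSeries) else np.asarray(series, float)
    if phi.size == 0:
        raise EmptyInputError("empty relative-phase series")
    r = np.exp(1j * np.radians(phi)).mean()
    return float(min(abs(r), 1.0))


def fisher_z(r: float) -> float:
    """Fisher transformation atanh(rho), clipped at 1 - 1e-6 to stay finite."""
    if not 0.0 <= r <= 1.0:
        raise ValidationError(f"rho must lie in [0, 1], got {r}")
    return float(np.arctanh(min(r, 1.0 - FISHER_EPS)))


def phase_coordination(
    pair: TrialPair, edge_discard_s: float = 1.0
) -> tuple[StabilityResult, RelativePhaseSeries]:
    """Full phase pipeline for one preprocessed trial.

    Hilbert phases for both actors, relative phase, then rho on the
    interior samples (``edge_discard_s`` seconds dropped at each end to
    avoid Hilbert edge effects).
    """
    p_phase = instantaneous_phase(pair.participant)
    a_phase = instantaneous_phase(pair.avatar)
    series = relative_phase(p_phase, a_phase)
    n_edge = int(round(edge_discard_s * pair.fs))
    n = len(series)
    if n > 2 * n_edge + 1:
        interior = series.phi_signed[n_edge : n - n_edge]
    else:
        interior = series.phi_signed
    r = rho(interior)
    return StabilityResult(rho=r, rho_z=fisher_z(r)), series
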