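"""Per-trial preprocessing of movement traces.

The chain applied to every trace before any coordination metric is
computed: remove the initial movement-onset transient, standardise the
trial to a common length, centre around zero, and low-pass filter
(zero-phase Butterworth). Defaults follow common practice for paced arm
movement recorded at 50 Hz: drop the first 6 s of a 90 s trial, keep 84 s,
and filter at 10 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigError, TooShortError
from .trace import MovementTrace, TrialPair

__all__ = [
    "PreprocessConfig",
    "trim_transient",
    "standardize_length",
    "center",
    "lowpass",
    "preprocess_trace",
    "preprocess_trial",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    trim_s : seconds removed from the start of each trial (transient).
    target_s : standardised trial length in seconds.
    cutoff_hz : low-pass corner frequency (must be below Nyquist).
    filter_order : Butterworth order, applied forward-backward so the
        effective magnitude response is the squared (doubled-order) one.
    """

    trim_s: float = 6.0
    target_s: float = 84.0
    cutoff_hz: float = 10.0
    filter_order: int = 2

    def __post_init__(self) -> None:
        if self.trim_s < 0:
            raise ConfigError("trim_s must be >= 0")
        if self.target_s <= 0:
            raise ConfigError("target_s must be > 0")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be > 0")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")


def trim_transient(trace: MovementTrace, trim_s: float = 6.0) -> MovementTrace:
    """Drop all samples with ``t < trim_s`` and re-zero the time axis."""
    if trim_s == 0:
        return trace
    if trace.duration <= trim_s:
        raise TooShortError(
            f"trace {trace.trial_id!r}/{trace.actor}: duration "
            f"{trace.duration:.3f} s <= trim {trim_s} s"
        )
    keep = trace.t - trace.t[0] >= trim_s - 1e-12
    t = trace.t[keep]
    return trace.with_data(t - t[0], trace.x[keep])


def standardize_length(trace: MovementTrace, target_s: float = 84.0) -> MovementTrace:
    """Standardise a trace to ``target_s`` seconds.

    Longer traces are truncated to the first ``target_s`` seconds; shorter
    ones are linearly resampled onto a uniform grid of ``round(target_s*fs)``
    samples spanning ``target_s``. Result duration is ``target_s`` within one
    sample period.
    """
    n_target = int(round(target_s * trace.fs))
    n = len(trace)
    if n == n_target:
        return trace
    if n > n_target:
        return trace.with_data(trace.t[:n_target], trace.x[:n_target])
    # shorter: stretch onto the target grid
    t_new = np.arange(n_target) / trace.fs
    scale = trace.duration / target_s
    x_new = np.interp(t_new * scale, trace.t - trace.t[0], trace.x)
    return trace.with_data(t_new, x_new)


def center(trace: MovementTrace) -> MovementTrace:
    """Subtract the mean so the series is centred around 0."""
    return trace.with_data(trace.t, trace.x - np.mean(trace.x))


def lowpass(trace: MovementTrace, cutoff_hz: float = 10.0, order: int = 2) -> MovementTrace:
    """Zero-phase Butterworth low-pass (forward-backward, length preserved)."""
    if cutoff_hz >= trace.fs / 2:
        raise ConfigError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {trace.fs / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos, trace.x)
    return trace.with_data(trace.t, x)


def preprocess_trace(trace: MovementTrace, config: PreprocessConfig | None = None) -> MovementTrace:
    """Apply trim -> standardize -> center -> filter to one trace."""
    cfg = config or PreprocessConfig()
    out = trim_transient(trace, cfg.trim_s)
    out = standardize_length(out, cfg.target_s)
    out = center(out)
    out = lowpass(out, cfg.cutoff_hz, cfg.filter_order)
    return out


def preprocess_trial(pair: TrialPair, config: PreprocessConfig | None = None) -> TrialPair:
    """Preprocess both actors of a trial; errors identify the failing actor."""
    cfg = config or PreprocessConfig()
    out = {}
    for name in ("participant", "avatar"):
        try:
            out[name] = preprocess_trace(getattr(pair, name), cfg)
        except TooShortError as exc:
            raise TooShortError(f"{name}: {exc}") from exc
    return replace(pair, participant=out["participant"], avatar=out["avatar"])
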