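"""Participant gaze: proportion of a trial spent looking at the avatar.

Gaze is recorded as an area-of-interest (AOI) hit series with labels
``avatar`` / ``room`` / ``missing`` (blinks, tracking loss). The per-trial
index is the fraction of samples on the avatar; by default missing samples
are excluded from the denominator, the standard eye-tracking convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, UndefinedProportionError, ValidationError

__all__ = ["AOISeries", "gaze_proportion", "trim_aoi"]

AOI_LABELS = ("avatar", "room", "missing")


@dataclass
class AOISeries:
    """Per-sample AOI labels on a non-decreasing time grid."""

    t: np.ndarray
    aoi: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.aoi = np.asarray(self.aoi, dtype=object)
        if len(self.t) != len(self.aoi):
            raise ValidationError("t and aoi must have equal length")
        if len(self.t) == 0:
            raise EmptyInputError("empty AOI series")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("AOI time must be non-decreasing")
        bad = set(self.aoi) - set(AOI_LABELS)
        if bad:
            raise ValidationError(f"unknown AOI labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.aoi)


def trim_aoi(series: AOISeries, start_s: float, end_s: float) -> AOISeries:
    """Restrict an AOI series to the window [start_s, end_s) (trial time)."""
    t0 = series.t - series.t[0]
    keep = (t0 >= start_s - 1e-12) & (t0 < end_s - 1e-12)
    if not np.any(keep):
        raise EmptyInputError("AOI trim window contains no samples")
    return AOISeries(t=series.t[keep] - series.t[keep][0], aoi=series.aoi[keep])


def gaze_proportion(series: AOISeries, missing_policy: str = "exclude") -> float:
    """Proportion of samples in which gaze fell on the avatar.

    missing_policy ``"exclude"`` drops missing samples from the
    denominator; ``"as_room"`` keeps them in the denominator (counting them
    as not-on-avatar).
    """
    if missing_policy not in ("exclude", "as_room"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    labels = series.aoi
    n_avatar = int(np.sum(labels == "avatar"))
    if missing_policy == "exclude":
        denom = int(np.sum(labels != "missing"))
    else:
        denom = len(labels)
    if denom == 0:
        raise UndefinedProportionError(
            "every AOI sample is missing; gaze proportion undefined"
        )
    return n_avatar / denom
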