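"""CSV readers and writers for the pipeline's external formats.

Dialects (all UTF-8, comma-separated, '.' decimal):

* movement, single actor:  header ``t,x``
* movement, combined pair: header ``t,participant,avatar``
* area-of-interest (gaze): header ``t,aoi`` with aoi in {avatar, room, missing}
  (``1``/``0`` accepted as aliases for avatar/room)
* covariates: header ``participant_id,gaze_condition,lsas,aq``
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError
from .gaze import AOISeries
from .trace import TIME_TOL, MovementTrace, TrialPair

log = logging.getLogger(__name__)

__all__ = [
    "read_movement_csv",
    "read_pair_csv",
    "read_aoi_csv",
    "read_covariates_csv",
    "write_movement_csv",
    "write_pair_csv",
    "write_aoi_csv",
    "write_covariates_csv",
]


def _trace_from_columns(t, x, *, trial_id: str, actor: str, source: str) -> MovementTrace:
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 2:
        raise EmptyInputError(f"{source}: fewer than 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{source}: non-finite displacement values")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError(f"{source}: timestamps not strictly increasing")
    step = float(np.median(dt))
    fs = 1.0 / step
    if np.max(np.abs(dt - step)) > TIME_TOL:
        # jittered grid: resample to the median rate with linear interpolation
        n = int(round((t[-1] - t[0]) / step)) + 1
        tu = t[0] + np.arange(n) * step
        x = np.interp(tu, t, x)
        t = tu
        log.warning(
            "%s: non-uniform sampling beyond %.0e s; resampled to %.6g Hz",
            source, TIME_TOL, fs,
        )
    return MovementTrace(t=t, x=x, fs=fs, trial_id=trial_id, actor=actor)


def _read_numeric_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in required:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col!r} is not numeric") from exc
    return df


def read_movement_csv(path, trial_id: str = "", actor: str = "participant") -> MovementTrace:
    """Read a single-actor movement CSV (``t,x``).

    The sample rate is inferred from the median time step; timestamps that
    deviate from a uniform grid by more than the tolerance are linearly
    resampled onto the median-rate grid (a warning is logged).
    """
    df = _read_numeric_csv(path, ("t", "x"))
    return _trace_from_columns(
        df["t"].to_numpy(), df["x"].to_numpy(),
        trial_id=trial_id or Path(path).stem, actor=actor, source=str(path),
    )


def read_pair_csv(
    path,
    gaze_condition: str = "direct",
    coordination: str = "spontaneous",
    trial_id: str = "",
) -> TrialPair:
    """Read a combined movement CSV (``t,participant,avatar``)."""
    df = _read_numeric_csv(path, ("t", "participant", "avatar"))
    tid = trial_id or Path(path).stem
    t = df["t"].to_numpy()
    p = _trace_from_columns(t, df["participant"].to_numpy(),
                            trial_id=tid, actor="participant", source=str(path))
    a = _trace_from_columns(t, df["avatar"].to_numpy(),
                            trial_id=tid, actor="avatar", source=str(path))
    return TrialPair(participant=p, avatar=a, gaze_condition=gaze_condition,
                     coordination=coordination, trial_id=tid)


_AOI_ALIASES = {"1": "avatar", "0": "room", "avatar": "avatar", "room": "room",
                "missing": "missing", "nan": "missing", "": "missing"}


def read_aoi_csv(path) -> AOISeries:
    """Read an area-of-interest hit series (``t,aoi``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"aoi": str}, keep_default_na=False)
    for col in ("t", "aoi"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: empty AOI series")
    labels = []
    for raw in df["aoi"].astype(str).str.strip().str.lower():
        if raw not in _AOI_ALIASES:
            raise FormatError(f"{path}: unknown AOI label {raw!r}")
        labels.append(_AOI_ALIASES[raw])
    t = pd.to_numeric(df["t"]).to_numpy(dtype=float)
    return AOISeries(t=t, aoi=np.array(labels, dtype=object))


def read_covariates_csv(path) -> pd.DataFrame:
    """Read the per-participant covariate table."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ("participant_id", "gaze_condition", "lsas", "aq")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad = set(df["gaze_condition"]) - {"direct", "averted"}
    if bad:
        raise FormatError(f"{path}: unknown gaze_condition values {sorted(bad)}")
    return df


def write_movement_csv(trace: MovementTrace, path) -> None:
    pd.DataFrame({"t": trace.t, "x": trace.x}).to_csv(path, index=False)


def write_pair_csv(pair: TrialPair, path) -> None:
    pd.DataFrame({
        "t": pair.participant.t,
        "participant": pair.participant.x,
        "avatar": pair.avatar.x,
    }).to_csv(path, index=False)


def write_aoi_csv(series: AOISeries, path) -> None:
    pd.DataFrame({"t": series.t, "aoi": series.aoi}).to_csv(path, index=False)


def write_covariates_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
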