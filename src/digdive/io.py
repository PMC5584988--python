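"""Readers and writers for trajectory CSVs and ethogram TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChamberGeometry, Mode, ModeTrack, Trajectory
from .errors import FormatError, ValidationError

__all__ = ["read_trajectory", "write_trajectory", "write_ethogram", "read_ethogram"]

_REQUIRED_COLUMNS = ("time_s", "x_mm", "z_mm")


def read_trajectory(path: str | Path, geometry: ChamberGeometry) -> Trajectory:
    """Read one trial's centroid trajectory from CSV.

    The file must carry a header with columns ``time_s,x_mm,z_mm``; an
    optional ``missing`` column (0/1) marks undetected frames, whose
    x/z entries may be empty.  Depths of non-missing frames must lie
    within the plausible band of ``geometry``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    raw = df[list(_REQUIRED_COLUMNS)]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # empty fields mean "no detection"; non-empty non-numeric fields are errors
    garbage = (numeric.isna() & ~raw.isna()).any(axis=1).to_numpy()
    if garbage.any():
        raise ValidationError(
            f"{path}: non-numeric values in rows {np.nonzero(garbage)[0][:5]}"
        )
    if "missing" in df.columns:
        missing = df["missing"].astype(bool).to_numpy()
    else:
        missing = numeric[["x_mm", "z_mm"]].isna().any(axis=1).to_numpy()
    if numeric["time_s"].isna().any():
        raise ValidationError(f"{path}: missing time values")

    times = numeric["time_s"].to_numpy()
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise ValidationError(f"{path}: time_s must be strictly increasing")

    x = numeric["x_mm"].to_numpy()
    z = numeric["z_mm"].to_numpy()
    x = np.where(missing, 0.0, x)
    z = np.where(missing, 0.0, z)
    trial_id = str(df["trial_id"].iloc[0]) if "trial_id" in df.columns and len(df) else path.stem
    interp = df["interpolated"].astype(bool).to_numpy() if "interpolated" in df.columns else None
    traj = Trajectory(trial_id=trial_id, times=times, x=x, z=z, missing=missing, interpolated=interp)
    traj.validate_bounds(geometry)
    return traj


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write a trajectory to CSV; inverse of :func:`read_trajectory`."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trajectory.times,
            "x_mm": trajectory.x,
            "z_mm": trajectory.z,
            "missing": trajectory.missing.astype(int),
            "interpolated": trajectory.interpolated.astype(int),
            "trial_id": trajectory.trial_id,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def write_ethogram(modetracks: list[ModeTrack], path: str | Path) -> Path:
    """Write a cohort ethogram as TSV, one row per trial.

    Rows are ordered by ascending total diving time, matching the
    convention used for ethogram figures; the first field is the trial
    id, the remaining fields are single-character mode codes, one per
    frame.
    """
    if not modetracks:
        raise ValidationError("cannot write an ethogram for an empty cohort")
    order = sorted(
        range(len(modetracks)),
        key=lambda i: (modetracks[i].total_time_in(Mode.DIVING), i),
    )
    path = Path(path)
    with path.open("w") as fh:
        for i in order:
            mt = modetracks[i]
            fh.write(mt.trial_id + "\t" + "\t".join(mt.labels.tolist()) + "\n")
    return path


def read_ethogram(path: str | Path, dt: float = 1.0) -> list[ModeTrack]:
    """Read an ethogram TSV back into bare ModeTracks (times rebuilt at dt)."""
    tracks = []
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        trial_id, codes = fields[0], fields[1:]
        times = np.arange(len(codes)) * dt
        tracks.append(ModeTrack(trial_id=trial_id, times=times, labels=np.array(codes)))
    return tracks
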