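"""Dive-event extraction and trial/cohort behavioral metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Mode, ModeTrack, Trajectory, TrialSummary
from .errors import ValidationError

__all__ = [
    "DiveEvent",
    "ModeProbabilitySeries",
    "extract_dives",
    "mode_time_fractions",
    "sliding_mode_probability",
    "post_dive_intervals",
    "correlate",
    "ecdf",
    "trial_summary",
    "cohort_summary",
    "cohort_aggregates",
]


@dataclass(frozen=True)
class DiveEvent:
    """One maximal contiguous run of diving frames."""

    trial_id: str
    start_s: float
    end_s: float
    duration_s: float
    max_depth_mm: float  # most negative z during the event
    mean_speed_mm_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("dive duration must be positive")


@dataclass(frozen=True)
class ModeProbabilitySeries:
    """Across-trial probability of a mode over time, window-smoothed."""

    times: np.ndarray
    probability: np.ndarray
    window_s: float
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        p = self.probability[np.isfinite(self.probability)]
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValidationError("probabilities must lie in [0, 1]")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def extract_dives(
    modetrack: ModeTrack,
    trajectory: Trajectory,
    speed: str = "path",
) -> list[DiveEvent]:
    """Run-length encode the label track into dive events.

    Duration is the frame count times the sampling interval; maximum
    depth is the most negative z inside the run.  Mean speed averages
    per-frame centroid increments within the run: path speed
    sqrt(dx^2 + dz^2)/dt by default, vertical |dz|/dt with
    ``speed='vertical'``; single-frame dives have no within-run
    increment and get NaN speed.
    """
    if len(modetrack) == 0:
        raise ValidationError("empty ModeTrack")
    if speed not in ("path", "vertical"):
        raise ValidationError(f"unknown speed definition {speed!r}")
    dt_arr = np.diff(trajectory.times)
    events = []
    for start, end in _runs(modetrack.labels == Mode.DIVING.value):
        dur = float(modetrack.times[end] - modetrack.times[start]) + modetrack.dt
        if end > start:
            dz = np.diff(trajectory.z[start : end + 1])
            dx = np.diff(trajectory.x[start : end + 1])
            inc = np.hypot(dx, dz) if speed == "path" else np.abs(dz)
            v = float(np.mean(inc / dt_arr[start:end]))
        else:
            v = float("nan")
        events.append(
            DiveEvent(
                trial_id=modetrack.trial_id,
                start_s=float(modetrack.times[start]),
                end_s=float(modetrack.times[start]) + dur,
                duration_s=dur,
                max_depth_mm=float(trajectory.z[start : end + 1].min()),
                mean_speed_mm_s=v,
            )
        )
    return events


def mode_time_fractions(modetrack: ModeTrack) -> dict[Mode, float]:
    """Percentage of non-excluded time per mode; sums to exactly 100."""
    active = modetrack.active
    n = int(np.count_nonzero(active))
    if n == 0:
        raise ValidationError("all frames are excluded")
    out = {}
    for mode in (Mode.SURFACING, Mode.DIGGING, Mode.DIVING, Mode.ESCAPING):
        out[mode] = 100.0 * np.count_nonzero(modetrack.labels[active] == mode.value) / n
    return out


def sliding_mode_probability(
    modetracks: list[ModeTrack],
    mode: Mode,
    window_s: float = 60.0,
) -> ModeProbabilitySeries:
    """Across-trial probability of ``mode``, smoothed by a centered window.

    Per frame, the indicator of the mode is averaged over trials whose
    frame is not excluded, then a centered moving average of width
    ``window_s`` (truncated at the series edges) smooths the result.
    All trials must share the time base.
    """
    if not modetracks:
        raise ValidationError("empty cohort")
    times = modetracks[0].times
    for mt in modetracks[1:]:
        if len(mt) != len(times) or not np.allclose(mt.times, times):
            raise ValidationError("all trials must share a common time base")
    labels = np.stack([mt.labels for mt in modetracks])  # trials x frames
    active = labels != Mode.EXCLUDED.value
    ind = (labels == mode.value) & active
    n_active = active.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_raw = np.where(n_active > 0, ind.sum(axis=0) / np.maximum(n_active, 1), np.nan)

    dt = modetracks[0].dt
    half = max(0, int(round(window_s / dt)) // 2)
    n = len(times)
    smoothed = np.empty(n)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        seg = p_raw[lo:hi]
        seg = seg[np.isfinite(seg)]
        smoothed[t] = seg.mean() if seg.size else np.nan
    return ModeProbabilitySeries(
        times=times.copy(), probability=smoothed, window_s=window_s, n_trials=n_active
    )


def post_dive_intervals(modetrack: ModeTrack) -> list[tuple[float, float]]:
    """Pair each dive's duration with the surface interval that follows.

    The interval is the time spent in SURFACING or DIGGING between the
    dive's end and the next dive's start.  The last dive of a trial has
    a censored interval and is dropped.
    """
    dt = modetrack.dt
    dive_runs = _runs(modetrack.labels == Mode.DIVING.value)
    pairs = []
    for (s0, e0), (s1, _) in zip(dive_runs[:-1], dive_runs[1:]):
        dur = (e0 - s0 + 1) * dt
        between = modetrack.labels[e0 + 1 : s1]
        surf = np.count_nonzero(
            (between == Mode.SURFACING.value) | (between == Mode.DIGGING.value)
        ) * dt
        pairs.append((float(dur), float(surf)))
    return pairs


def correlate(pairs: list[tuple[float, float]], method: str = "spearman") -> tuple[float, float]:
    """Rank (or linear) correlation with a two-sided p-value.

    For Spearman with at most 8 pairs the p-value is computed by exact
    permutation enumeration; larger samples use the asymptotic
    approximation.  Degenerate inputs (constant margin) yield
    (nan, nan).
    """
    if len(pairs) < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan")
    if method == "spearman":
        res = stats.spearmanr(a, b)
        rho = float(res.statistic)
        if len(pairs) <= 8:
            return rho, _spearman_exact_p(a, b, rho)
        return rho, float(res.pvalue)
    if method == "pearson":
        res = stats.pearsonr(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown correlation method {method!r}")


def _spearman_exact_p(a: np.ndarray, b: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for the Spearman coefficient."""
    from itertools import permutations

    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    perms = np.array(list(permutations(rb)))
    ra_c = ra - ra.mean()
    pb = perms - rb.mean()
    num = pb @ ra_c
    den = np.sqrt((ra_c**2).sum() * (pb**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: (sorted unique support, fractions)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("ecdf needs at least one value")
    res = stats.ecdf(values)
    return res.cdf.quantiles, res.cdf.probabilities


def trial_summary(modetrack: ModeTrack, trajectory: Trajectory, speed: str = "path") -> TrialSummary:
    """Condense one trial into its behavioral metrics."""
    fractions = mode_time_fractions(modetrack)
    dives = extract_dives(modetrack, trajectory, speed=speed)
    durations = np.array([d.duration_s for d in dives])
    speeds = np.array([d.mean_speed_mm_s for d in dives])
    speeds = speeds[np.isfinite(speeds)]
    return TrialSummary(
        trial_id=modetrack.trial_id,
        pct_surfacing=fractions[Mode.SURFACING],
        pct_digging=fractions[Mode.DIGGING],
        pct_diving=fractions[Mode.DIVING],
        pct_escaping=fractions[Mode.ESCAPING],
        n_dives=len(dives),
        mean_dive_duration_s=float(durations.mean()) if dives else float("nan"),
        median_dive_duration_s=float(np.median(durations)) if dives else float("nan"),
        max_dive_depth_mm=float(min(d.max_depth_mm for d in dives)) if dives else float("nan"),
        mean_dive_speed_mm_s=float(speeds.mean()) if speeds.size else float("nan"),
        escaped=modetrack.escaped,
        excluded=modetrack.inactive_from is not None,
    )


def cohort_summary(
    modetracks: list[ModeTrack],
    trajectories: list[Trajectory],
    speed: str = "path",
) -> pd.DataFrame:
    """One row of behavioral metrics per non-excluded trial.

    Trials flagged inactive (``inactive_from`` set) are dropped;
    escaped trials are kept with their pre-escape frames.
    """
    if not modetracks:
        raise ValidationError("empty cohort")
    if len(modetracks) != len(trajectories):
        raise ValidationError("modetracks and trajectories must align")
    rows = []
    for mt, traj in zip(modetracks, trajectories):
        if mt.inactive_from is not None:
            continue
        s = trial_summary(mt, traj, speed=speed)
        rows.append(
            {
                "trial_id": s.trial_id,
                "pct_surfacing": s.pct_surfacing,
                "pct_digging": s.pct_digging,
                "pct_diving": s.pct_diving,
                "pct_escaping": s.pct_escaping,
                "n_dives": s.n_dives,
                "mean_dive_duration_s": s.mean_dive_duration_s,
                "median_dive_duration_s": s.median_dive_duration_s,
                "max_dive_depth_mm": s.max_dive_depth_mm,
                "mean_dive_speed_mm_s": s.mean_dive_speed_mm_s,
                "escaped": s.escaped,
            }
        )
    if not rows:
        raise ValidationError("every trial in the cohort was excluded as inactive")
    return pd.DataFrame(rows)


def cohort_aggregates(summary: pd.DataFrame) -> dict[str, float]:
    """Cohort-level mean +/- sd aggregates recomputed from per-trial rows."""
    agg = {
        "n_trials": float(len(summary)),
        "dives_per_trial_mean": float(summary["n_dives"].mean()),
        "dives_per_trial_sd": float(summary["n_dives"].std(ddof=1)) if len(summary) > 1 else float("nan"),
        "pct_diving_mean": float(summary["pct_diving"].mean()),
        "pct_digging_mean": float(summary["pct_digging"].mean()),
        "pct_surfacing_mean": float(summary["pct_surfacing"].mean()),
        "escaped_fraction": float(summary["escaped"].mean()),
    }
    durs = summary["mean_dive_duration_s"].dropna()
    agg["dive_duration_mean_s"] = float(durs.mean()) if len(durs) else float("nan")
    return agg
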