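"""Depth-density thresholding and per-frame behavioral classification.

The cohort depth distribution is multimodal: a dominant mode from
digging right under the gel surface and a long deep tail from dives.
The dive threshold is the first strict local minimum of the
kernel-smoothed depth density below the sample mean, scanned downward
(toward more negative depths).  The digging boundary is fixed at the
gel surface (z = 0).  Classification then partitions every frame:

    z > air_top            -> ESCAPING
    0 < z <= air_top       -> SURFACING
    z_diving < z <= 0      -> DIGGING
    z <= z_diving          -> DIVING

Escape and inactivity flags post-process the label track: a contiguous
out-of-arena run longer than 30 s marks the trial escaped and excludes
the remainder; a submerged animal whose displacement stays below a
small tolerance for the rest of the trial is excluded as inactive
(drowned animals freeze in place).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BehaviorThresholds, ChamberGeometry, Mode, ModeTrack, Trajectory
from .errors import NoMinimumError, ValidationError

__all__ = [
    "DensityEstimate",
    "silverman_bandwidth",
    "depth_pdf",
    "dive_threshold",
    "classify_modes",
    "flag_escape",
    "flag_inactive",
]


@dataclass(frozen=True)
class DensityEstimate:
    """A Gaussian-kernel density of pooled centroid depths on a uniform grid.

    The density is renormalized to unit trapezoidal integral over the
    grid (the grid truncates the far kernel tails).
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    sample_mean: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValidationError("density must be non-negative")
        integral = float(np.trapezoid(self.density, self.grid))
        if abs(integral - 1.0) > 1e-6:
            raise ValidationError(f"density integral {integral} != 1")


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * a * len(x) ** (-0.2)


def depth_pdf(
    depths: np.ndarray,
    bandwidth: float | str = "auto",
    grid_step: float = 0.05,
) -> DensityEstimate:
    """Gaussian-kernel KDE of pooled depths on a uniform grid.

    The grid spans the data range extended by 3 bandwidths on each
    side.  ``bandwidth='auto'`` applies Silverman's rule.
    """
    x = np.asarray(depths, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("depth_pdf needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("depths must be finite")
    if x.size < 100:
        warnings.warn(
            f"depth_pdf called with only {x.size} samples; the density may be unstable",
            stacklevel=2,
        )
    sd = float(np.std(x, ddof=1))
    if bandwidth == "auto":
        if sd == 0:
            raise ValidationError("cannot choose a bandwidth for constant data")
        h = silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValidationError("bandwidth must be positive")

    grid = np.arange(x.min() - 3 * h, x.max() + 3 * h + grid_step / 2, grid_step)
    if sd == 0:
        dens = stats.norm.pdf(grid, loc=x[0], scale=h)
    else:
        kde = stats.gaussian_kde(x, bw_method=h / sd)
        dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return DensityEstimate(grid=grid, density=dens, bandwidth=h, sample_mean=float(x.mean()))


def dive_threshold(density: DensityEstimate) -> float:
    """First strict local minimum of the depth density below the sample mean.

    Scans the grid downward (decreasing z) starting at the sample mean
    and returns the first grid point whose density is strictly lower
    than both neighbors.  Exact plateaus break toward the shallower
    (larger z) end.  Raises :class:`NoMinimumError` when the density is
    monotone below the mean — a caller with a configured default must
    apply it explicitly.
    """
    g, d = density.grid, density.density
    i0 = int(np.searchsorted(g, density.sample_mean, side="right")) - 1
    i0 = min(max(i0, 1), len(g) - 2)
    i = i0
    while i >= 1:
        if d[i] < d[i + 1]:
            # walk left across any exact plateau
            j = i
            while j >= 1 and d[j - 1] == d[i]:
                j -= 1
            if j >= 1 and d[j - 1] > d[i]:
                return float(g[i])  # shallower end of the plateau
            i = j - 1
        else:
            i -= 1
    raise NoMinimumError(
        "no strict local minimum of the depth density below the sample mean "
        f"({density.sample_mean:.3f} mm)"
    )


def classify_modes(
    trajectory: Trajectory,
    thresholds: BehaviorThresholds,
    geometry: ChamberGeometry | None = None,
) -> ModeTrack:
    """Assign a behavioral mode to every frame by its depth.

    Missing frames inherit the previous frame's label; a missing
    lead-in defaults to SURFACING (larvae are loaded at the top).
    """
    if geometry is None:
        geometry = ChamberGeometry()
    z = trajectory.z
    labels = np.where(
        z > geometry.air_top_z,
        Mode.ESCAPING.value,
        np.where(
            z > thresholds.z_digging,
            Mode.SURFACING.value,
            np.where(z > thresholds.z_diving, Mode.DIGGING.value, Mode.DIVING.value),
        ),
    ).astype("<U1")
    prev = Mode.SURFACING.value
    for i in range(len(labels)):
        if trajectory.missing[i]:
            labels[i] = prev
        else:
            prev = labels[i]
    return ModeTrack(trial_id=trajectory.trial_id, times=trajectory.times.copy(), labels=labels)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def flag_escape(modetrack: ModeTrack, min_out_duration: float = 30.0) -> ModeTrack:
    """Mark the trial escaped when a contiguous out-of-arena run exceeds 30 s.

    The run duration is the frame count times the sampling interval.
    From the start of the first qualifying run onward, frames are
    EXCLUDED from time-fraction denominators; the trial itself still
    counts (as escaped) in cohort tallies.
    """
    labels = modetrack.labels.copy()
    dt = modetrack.dt
    escaped = False
    for start, end in _runs(labels == Mode.ESCAPING.value):
        if (end - start + 1) * dt > min_out_duration:
            labels[start:] = Mode.EXCLUDED.value
            escaped = True
            break
    return ModeTrack(
        trial_id=modetrack.trial_id,
        times=modetrack.times.copy(),
        labels=labels,
        escaped=escaped,
        inactive_from=modetrack.inactive_from,
    )


def flag_inactive(
    trajectory: Trajectory,
    modetrack: ModeTrack,
    eps_mm: float = 0.2,
    window_s: float = 120.0,
) -> ModeTrack:
    """Exclude the terminal inactive (drowned) segment of a trial.

    A trial is inactive from t0 when, for every frame from t0 to the
    end, the animal is submerged (z <= 0) and the total centroid
    displacement inside the rolling window starting at that frame stays
    below ``eps_mm``.  The inactive tail must be at least one window
    long.  Frames from t0 onward become EXCLUDED and the trial is
    flagged for exclusion from cohort statistics via ``inactive_from``.
    """
    n = len(trajectory)
    if n < 2:
        return modetrack
    dt = trajectory.dt
    w = max(1, int(round(window_s / dt)))
    steps = np.hypot(np.diff(trajectory.x), np.diff(trajectory.z))
    csum = np.concatenate([[0.0], np.cumsum(steps)])  # csum[i] = path length up to frame i
    # disp[t] = path length within [t, t+w]
    idx_hi = np.minimum(np.arange(n) + w, n - 1)
    disp = csum[idx_hi] - csum[np.arange(n)]
    ok = (disp < eps_mm) & (trajectory.z <= 0.0) & ~trajectory.missing
    # longest all-ok suffix
    t0 = n
    for i in range(n - 1, -1, -1):
        if ok[i]:
            t0 = i
        else:
            break
    if t0 >= n or (n - t0) < w:
        return modetrack
    labels = modetrack.labels.copy()
    labels[t0:] = Mode.EXCLUDED.value
    return ModeTrack(
        trial_id=modetrack.trial_id,
        times=modetrack.times.copy(),
        labels=labels,
        escaped=modetrack.escaped,
        inactive_from=int(t0),
    )
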