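"""Semi-Markov simulator for larval dig-and-dive trajectories.

The generator produces 1 Hz depth/position traces with per-frame
ground-truth states for a 15 min trial in a 12 mm gel column topped by
a 2 mm air chamber.  The behavioral skeleton is a semi-Markov
alternation between surfacing and digging bouts with lognormal dwell
times, interrupted by dive excursions whose per-trial count is Poisson
with the configured rate.  Dives descend and ascend at a constant
vertical speed to a drawn maximum depth (triangular depth profile), so
the mean path speed of a dive is exactly the configured speed when
positional noise is off.  Time submerged below the dive threshold
beyond an aerobic limit accrues a per-second drowning hazard; a drowned
larva freezes in place for the rest of the trial.  Condition presets
encode the experimental groups (species, gel stiffness, odor, blocked
posterior spiracles) through shifts of these parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ChamberGeometry, Mode, Trajectory
from .errors import ConfigError, ValidationError

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "preset_params",
    "list_presets",
    "simulate_trial",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the semi-Markov dig-and-dive model.

    Dwell times are lognormal, parameterized by their arithmetic mean
    (seconds) and log-space shape sigma so that configured means are
    directly recoverable from simulated bouts.  ``dive_rate`` is the
    expected number of dive excursions per trial.  Depth targets are
    drawn from a normal truncated to (gel bottom, dive threshold].
    """

    condition_name: str = "custom"
    trial_length_s: float = 900.0
    dt_s: float = 1.0
    # surfacing / digging dwell-time distributions
    surface_dwell_mean_s: float = 60.0
    surface_dwell_shape: float = 0.8
    dig_dwell_mean_s: float = 90.0
    dig_dwell_shape: float = 0.8
    p_start_surfacing: float = 0.8
    # dive excursions
    dive_rate: float = 4.1
    dive_speed_mm_s: float = 0.4
    dive_depth_mean_mm: float = -6.5
    dive_depth_sd_mm: float = 1.5
    dive_threshold_mm: float = -3.6
    dive_bottom_dwell_mean_s: float = 0.0
    dive_bottom_dwell_shape: float = 0.6
    aerobic_limit_s: float = 180.0
    drown_hazard_per_s: float = 0.0
    # escape excursions above the air chamber
    escape_rate: float = 0.0
    escape_duration_mean_s: float = 45.0
    # within-bout positional noise
    horizontal_jitter_sd_mm: float = 0.05
    depth_jitter_sd_mm: float = 0.08
    # shallow-state depth dynamics: mean-reverting walk around the state level
    surface_level_mm: float = 1.0
    surface_level_sd_mm: float = 0.4
    dig_level_mean_mm: float = -1.6
    dig_level_sd_mm: float = 0.5
    level_reversion_rate: float = 0.08

    def __post_init__(self) -> None:
        if self.trial_length_s <= 0 or self.dt_s <= 0:
            raise ValidationError("trial_length_s and dt_s must be positive")
        if self.dive_rate < 0 or self.escape_rate < 0 or self.drown_hazard_per_s < 0:
            raise ValidationError("rates must be non-negative")
        if self.dive_speed_mm_s <= 0:
            raise ValidationError("dive_speed_mm_s must be positive")
        if self.surface_dwell_mean_s <= 0 or self.dig_dwell_mean_s <= 0:
            raise ValidationError("dwell means must be positive")
        if self.dive_depth_mean_mm > self.dive_threshold_mm:
            raise ValidationError(
                "dive_depth_mean_mm must lie at or below the dive threshold"
            )
        if self.horizontal_jitter_sd_mm < 0 or self.depth_jitter_sd_mm < 0:
            raise ValidationError("jitter standard deviations must be non-negative")


@dataclass
class GroundTruth:
    """True per-frame states and dive episodes emitted by the simulator."""

    states: np.ndarray  # single-character mode codes, aligned with the trajectory
    dives: list[tuple[int, int, float]] = field(default_factory=list)
    # (start_idx, end_idx inclusive, max depth mm) for contiguous z <= threshold runs
    drowned_at: float | None = None

    def n_dives(self) -> int:
        return len(self.dives)


# ---------------------------------------------------------------------------
# Condition presets
#
# Anchors are cohort means for calibration: dives/trial 4.1 (melanogaster,
# 0.4% gel, no odor), 5.3 (with ethyl acetate), 0.3 (blocked posterior
# spiracles), 1.9 (suzukii 0.4%), 1.0 (suzukii blocked); suzukii single-dive
# durations about tenfold melanogaster's; soft (0.05%) and hard (2.0%) gels
# are surface-dominated for melanogaster.
# ---------------------------------------------------------------------------

_MEL_BASE = SimulationParams(
    condition_name="mel_0.4_noodor",
    surface_dwell_mean_s=35.0,
    dig_dwell_mean_s=140.0,
    dive_rate=4.1,
    dive_speed_mm_s=0.4,
    dive_depth_mean_mm=-6.5,
    dive_depth_sd_mm=1.2,
    dive_threshold_mm=-3.6,
    dive_bottom_dwell_mean_s=8.0,
    aerobic_limit_s=180.0,
    drown_hazard_per_s=0.005,
    dig_level_mean_mm=-2.1,
    dig_level_sd_mm=0.5,
)

_PRESETS: dict[str, SimulationParams] = {
    "mel_0.4_noodor": _MEL_BASE,
    # appetitive odor below: more, deeper and longer dives
    "mel_0.4_odor": replace(
        _MEL_BASE,
        condition_name="mel_0.4_odor",
        dive_rate=5.3,
        dive_depth_mean_mm=-8.2,
        dive_depth_sd_mm=1.0,
        dive_bottom_dwell_mean_s=16.0,
    ),
    # blocked posterior spiracles: digging and diving suppressed
    "mel_blocked": replace(
        _MEL_BASE,
        condition_name="mel_blocked",
        dive_rate=0.3,
        surface_dwell_mean_s=300.0,
        dig_dwell_mean_s=45.0,
    ),
    # second species: fewer dives, roughly tenfold longer, hypoxia-tolerant
    "suzukii_0.4": replace(
        _MEL_BASE,
        condition_name="suzukii_0.4",
        dive_rate=1.9,
        dive_speed_mm_s=0.12,
        dive_depth_mean_mm=-6.5,
        dive_depth_sd_mm=0.8,
        dive_threshold_mm=-3.4,
        dive_bottom_dwell_mean_s=150.0,
        aerobic_limit_s=600.0,
        drown_hazard_per_s=0.002,
        surface_dwell_mean_s=45.0,
        dig_dwell_mean_s=120.0,
        dig_level_mean_mm=-2.0,
    ),
    "suzukii_blocked": replace(
        _MEL_BASE,
        condition_name="suzukii_blocked",
        dive_rate=1.0,
        dive_speed_mm_s=0.12,
        dive_depth_mean_mm=-6.0,
        dive_depth_sd_mm=0.8,
        dive_threshold_mm=-3.4,
        dive_bottom_dwell_mean_s=80.0,
        aerobic_limit_s=400.0,
        drown_hazard_per_s=0.002,
        surface_dwell_mean_s=220.0,
        dig_dwell_mean_s=60.0,
    ),
    # very soft gel: surface-dominated, rare deep dives that often drown
    "mel_soft_0.05": replace(
        _MEL_BASE,
        condition_name="mel_soft_0.05",
        dive_rate=0.3,
        dive_speed_mm_s=0.1,
        dive_depth_mean_mm=-9.0,
        dive_depth_sd_mm=1.5,
        dive_bottom_dwell_mean_s=20.0,
        aerobic_limit_s=60.0,
        drown_hazard_per_s=0.05,
        surface_dwell_mean_s=400.0,
        dig_dwell_mean_s=40.0,
        surface_level_mm=1.7,
    ),
    # hard gel: resting at the surface with short digging episodes
    "mel_hard_2.0": replace(
        _MEL_BASE,
        condition_name="mel_hard_2.0",
        dive_rate=0.05,
        dive_depth_mean_mm=-4.8,
        dive_depth_sd_mm=0.5,
        dive_bottom_dwell_mean_s=4.0,
        aerobic_limit_s=120.0,
        surface_dwell_mean_s=260.0,
        dig_dwell_mean_s=55.0,
    ),
}


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def preset_params(condition: str) -> SimulationParams:
    """Return the parameter set for a named experimental condition."""
    try:
        return _PRESETS[condition]
    except KeyError:
        raise ConfigError(
            f"unknown condition preset {condition!r}; available: {list_presets()}"
        ) from None


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------


def _lognormal_dwell(rng: np.random.Generator, mean_s: float, shape: float) -> float:
    mu = np.log(mean_s) - 0.5 * shape**2
    return float(rng.lognormal(mu, shape))


def _dive_profile(
    z0: float, depth: float, v: float, dt: float, bottom_frames: int = 0
) -> np.ndarray:
    """Depth profile of one dive: descend at v, search the bottom, ascend at v.

    The target depth is snapped to the speed grid so every per-frame
    transit increment is exactly v*dt; with ``bottom_frames`` = 0 the
    profile is purely triangular and the mean path speed of the
    excursion is identically v.  Bottom-search frames hold the maximum
    depth (the animal probes the substrate without net vertical
    motion), which is what puts a deep occupancy mode into the cohort
    depth density.
    """
    steps = max(1, round((z0 - depth) / (v * dt)))
    down = z0 - v * dt * np.arange(1, steps + 1)
    bottom = np.full(bottom_frames, down[-1])
    up = down[-1] + v * dt * np.arange(1, steps + 1)
    return np.concatenate([down, bottom, up])


def _background_bouts(
    rng: np.random.Generator, params: SimulationParams, n: int, geometry: ChamberGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating surfacing/digging skeleton covering n frames.

    Within a bout, depth follows a mean-reverting walk around the
    state's typical level (larvae wander slowly while resting or
    digging) with small independent frame-to-frame jitter on top,
    clipped to the state's depth band.
    """
    dt = params.dt_s
    z = np.empty(n)
    states = np.empty(n, dtype="<U1")
    t = 0
    surfacing = bool(rng.random() < params.p_start_surfacing)
    z_div = params.dive_threshold_mm
    theta = min(1.0, params.level_reversion_rate * dt)
    while t < n:
        if surfacing:
            dwell = _lognormal_dwell(rng, params.surface_dwell_mean_s, params.surface_dwell_shape)
            mu, sd = params.surface_level_mm, params.surface_level_sd_mm
            code = Mode.SURFACING.value
            lo, hi = 0.05, geometry.air_top_z - 0.05
        else:
            dwell = _lognormal_dwell(rng, params.dig_dwell_mean_s, params.dig_dwell_shape)
            mu, sd = params.dig_level_mean_mm, params.dig_level_sd_mm
            code = Mode.DIGGING.value
            lo, hi = z_div + 0.05, -0.05
        k = min(max(1, round(dwell / dt)), n - t)
        phi = 1.0 - theta
        sigma_e = sd * np.sqrt(max(0.0, 1.0 - phi**2))
        seg = np.empty(k)
        cur = float(np.clip(rng.normal(mu, sd), lo, hi))
        eps = rng.normal(0.0, 1.0, size=k)
        for i in range(k):
            cur = mu + phi * (cur - mu) + sigma_e * eps[i]
            cur = float(np.clip(cur, lo, hi))
            seg[i] = cur
        if params.depth_jitter_sd_mm > 0:
            seg = seg + rng.normal(0.0, params.depth_jitter_sd_mm, size=k)
        z[t : t + k] = np.clip(seg, lo, hi)
        states[t : t + k] = code
        t += k
        surfacing = not surfacing
    return z, states


def simulate_trial(
    params: SimulationParams,
    geometry: ChamberGeometry | None = None,
    seed: int | np.random.SeedSequence = 0,
    trial_id: str | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one 15 min trial; deterministic for a given seed.

    Returns the 1 Hz trajectory and its ground truth.  True states
    follow the same depth partition the classifier uses, with the dive
    threshold taken from ``params.dive_threshold_mm``: escape above the
    air-chamber top, surfacing in (0, top], digging in (threshold, 0],
    diving at or below the threshold.
    """
    if geometry is None:
        geometry = ChamberGeometry()
    rng = np.random.default_rng(seed)
    dt = params.dt_s
    n = int(round(params.trial_length_s / dt))
    times = np.arange(n) * dt

    z, states = _background_bouts(rng, params, n, geometry)
    # horizontal wander: mean-reverting walk about the chamber centerline
    # (the narrow chamber lets larvae drift sideways and turn around but
    # not run along x), innovation sd = horizontal_jitter_sd_mm per frame
    x = np.empty(n)
    x_lim = geometry.chamber_width / 2 - 0.3
    cur = 0.0
    for i in range(n):
        cur = 0.98 * cur + rng.normal(0.0, params.horizontal_jitter_sd_mm)
        cur = float(np.clip(cur, -x_lim, x_lim))
        x[i] = cur

    # --- escape excursion -------------------------------------------------
    if rng.random() < params.escape_rate:
        dur = max(2, round(_lognormal_dwell(rng, params.escape_duration_mean_s, 0.4) / dt))
        start = int(rng.integers(0, max(1, n - dur)))
        k = min(dur, n - start)
        lvl = geometry.air_top_z + 0.8
        z[start : start + k] = lvl + rng.normal(0.0, 0.1, size=k)
        states[start : start + k] = Mode.ESCAPING.value

    # --- dive excursions --------------------------------------------------
    n_dives = int(rng.poisson(params.dive_rate))
    v = params.dive_speed_mm_s
    profiles: list[np.ndarray] = []
    for _ in range(n_dives):
        depth = rng.normal(params.dive_depth_mean_mm, params.dive_depth_sd_mm)
        depth = float(np.clip(depth, geometry.gel_bottom_z + 0.3, params.dive_threshold_mm - 0.3))
        z0 = float(np.clip(rng.normal(params.dig_level_mean_mm, 0.3), params.dive_threshold_mm + 0.6, -0.2))
        bottom = 0
        if params.dive_bottom_dwell_mean_s > 0:
            bottom = round(
                _lognormal_dwell(
                    rng, params.dive_bottom_dwell_mean_s, params.dive_bottom_dwell_shape
                )
                / dt
            )
        profiles.append(_dive_profile(z0, depth, v, dt, bottom_frames=bottom))
    # keep dives that fit; place without overlap via uniform spacers
    while profiles and sum(len(p) for p in profiles) >= n - 2:
        profiles.pop()
    if profiles:
        total = sum(len(p) for p in profiles)
        free = n - total
        offsets = np.sort(rng.integers(0, free, size=len(profiles)))
        cum = 0
        for off, prof in zip(offsets, profiles):
            start = int(off + cum)
            k = len(prof)
            z[start : start + k] = prof
            cum += k

    # relabel purely by depth so states and positions are consistent by
    # construction (dive transit frames above the threshold count as digging)
    below = z <= params.dive_threshold_mm
    states = np.where(
        z > geometry.air_top_z,
        Mode.ESCAPING.value,
        np.where(
            z > 0.0,
            Mode.SURFACING.value,
            np.where(below, Mode.DIVING.value, Mode.DIGGING.value),
        ),
    ).astype("<U1")

    # x frozen during dives: the chamber constrains dives to the vertical axis
    drowned_at: float | None = None
    runs = _runs_of(below)
    for start, end in runs:
        if start > 0:
            x[start : end + 1] = x[start - 1]
        else:
            x[: end + 1] = x[0]
    # --- drowning hazard beyond the aerobic limit -------------------------
    if params.drown_hazard_per_s > 0:
        for start, end in runs:
            limit_frames = int(round(params.aerobic_limit_s / dt))
            for k in range(start + limit_frames, end + 1):
                if rng.random() < params.drown_hazard_per_s * dt:
                    z[k:] = z[k]
                    x[k:] = x[k]
                    states[k:] = Mode.DIVING.value if z[k] <= params.dive_threshold_mm else states[k]
                    drowned_at = float(times[k])
                    break
            if drowned_at is not None:
                break

    below = z <= params.dive_threshold_mm
    dives = [
        (s, e, float(z[s : e + 1].min())) for s, e in _runs_of(below)
    ]
    traj = Trajectory(trial_id=trial_id or f"{params.condition_name}", times=times, x=x, z=z)
    return traj, GroundTruth(states=states, dives=dives, drowned_at=drowned_at)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def simulate_cohort(
    params: SimulationParams,
    n_trials: int,
    seed: int = 0,
    geometry: ChamberGeometry | None = None,
) -> list[tuple[Trajectory, GroundTruth]]:
    """Simulate ``n_trials`` independent trials.

    Per-trial seeds are derived as ``SeedSequence((seed, index))``, so
    trial i is reproducible independently of cohort size or order.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be at least 1")
    out = []
    for i in range(n_trials):
        ss = np.random.SeedSequence((seed, i))
        traj, gt = simulate_trial(
            params, geometry=geometry, seed=ss,
            trial_id=f"{params.condition_name}_{i:03d}",
        )
        out.append((traj, gt))
    return out
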