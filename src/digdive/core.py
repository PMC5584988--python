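"""Domain types and coordinate conventions.

The spatial datum is the gel surface: z = 0 mm at the agarose/air
interface, positive z up into the air chamber, negative z down into the
gel.  All modules share this frame.  Sampling is nominally 1 Hz; every
duration is computed from timestamps, never from raw frame counts times
an assumed rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "Mode",
    "MODE_CODES",
    "ChamberGeometry",
    "Trajectory",
    "BehaviorThresholds",
    "ModeTrack",
    "TrialSummary",
]


class Mode(str, enum.Enum):
    """Per-frame behavioral mode.

    Single-character codes are the on-disk ethogram alphabet:
    S surfacing, G digging, V diving, E escaping, X excluded.
    """

    SURFACING = "S"
    DIGGING = "G"
    DIVING = "V"
    ESCAPING = "E"
    EXCLUDED = "X"

    @property
    def code(self) -> str:
        return self.value


MODE_CODES = tuple(m.value for m in Mode)


@dataclass(frozen=True)
class ChamberGeometry:
    """Geometry of one dig-and-dive chamber.

    The gel column is 12 mm deep and 3 mm wide with a 2 mm air chamber
    above it.  ``px_per_mm`` plus the pixel row of the gel surface
    (``surface_row``) and the pixel column of the chamber centerline
    (``center_col``) calibrate the renderer/tracker mapping; the latter
    two stay ``None`` until a frame layout is attached.
    """

    gel_surface_z: float = 0.0
    gel_bottom_z: float = -12.0
    air_top_z: float = 2.0
    chamber_width: float = 3.0
    px_per_mm: float = 10.0
    surface_row: float | None = None
    center_col: float | None = None

    def __post_init__(self) -> None:
        if not (self.gel_bottom_z < self.gel_surface_z < self.air_top_z):
            raise ValidationError(
                "require gel_bottom_z < gel_surface_z < air_top_z, got "
                f"{self.gel_bottom_z}, {self.gel_surface_z}, {self.air_top_z}"
            )
        if self.px_per_mm <= 0:
            raise ValidationError("px_per_mm must be positive")
        if self.chamber_width <= 0:
            raise ValidationError("chamber_width must be positive")


@dataclass
class Trajectory:
    """Per-second centroid positions of one larva.

    ``missing`` marks frames with no detection; ``interpolated`` marks
    frames filled in by the tracker's short-gap interpolation (a subset
    of frames that were originally missing).
    """

    trial_id: str
    times: np.ndarray
    x: np.ndarray
    z: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]
    interpolated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.times)
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.x) == len(self.z) == len(self.missing) == n):
            raise ValidationError("times, x, z and masks must have equal length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        ok = ~self.missing
        if not np.all(np.isfinite(self.z[ok])):
            raise ValidationError("non-missing z must be finite")
        if not np.all(np.isfinite(self.x[ok])):
            raise ValidationError("non-missing x must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        if len(self.times) < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))

    def validate_bounds(self, geometry: ChamberGeometry) -> None:
        """Check non-missing depths lie inside the physically plausible band.

        Escape excursions may exceed the air-chamber top, so the upper
        slack is generous (+5 mm); the lower slack is 1 mm below the gel
        bottom.
        """
        ok = ~self.missing
        lo = geometry.gel_bottom_z - 1.0
        hi = geometry.air_top_z + 5.0
        if np.any(self.z[ok] < lo) or np.any(self.z[ok] > hi):
            raise ValidationError(
                f"depths outside [{lo}, {hi}] mm for trial {self.trial_id!r}"
            )


@dataclass(frozen=True)
class BehaviorThresholds:
    """Depth boundaries between the elementary modes.

    ``z_digging`` is fixed at the gel surface; ``z_diving`` is estimated
    from the cohort depth density (first local minimum below the mean).
    """

    z_diving: float
    z_digging: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_diving < self.z_digging:
            raise ValidationError(
                f"z_diving ({self.z_diving}) must lie below z_digging ({self.z_digging})"
            )


@dataclass
class ModeTrack:
    """Per-frame behavioral labels for one trial."""

    trial_id: str
    times: np.ndarray
    labels: np.ndarray  # array of single-character codes, dtype <U1
    escaped: bool = False
    inactive_from: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U1")
        if len(self.labels) != len(self.times):
            raise ValidationError("labels and times must have equal length")
        bad = set(np.unique(self.labels)) - set(MODE_CODES)
        if bad:
            raise ValidationError(f"unknown mode codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of frames that enter time-fraction denominators."""
        return self.labels != Mode.EXCLUDED.value

    def total_time_in(self, mode: Mode) -> float:
        """Total seconds spent in ``mode`` (frame count x sampling interval)."""
        return float(np.count_nonzero(self.labels == mode.value)) * self.dt


@dataclass
class TrialSummary:
    """Per-trial behavioral metrics (one ethogram row condensed)."""

    trial_id: str
    pct_surfacing: float
    pct_digging: float
    pct_diving: float
    pct_escaping: float
    n_dives: int
    mean_dive_duration_s: float
    median_dive_duration_s: float
    max_dive_depth_mm: float
    mean_dive_speed_mm_s: float
    escaped: bool
    excluded: bool = False
    percentages: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.percentages = {
            Mode.SURFACING: self.pct_surfacing,
            Mode.DIGGING: self.pct_digging,
            Mode.DIVING: self.pct_diving,
            Mode.ESCAPING: self.pct_escaping,
        }
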