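"""Synthetic frame renderer: draws the chamber and larva as 8-bit images.

Provides the closed-loop fixture for the centroid tracker: a trajectory
is rendered as a stack of grayscale frames (one per sample) with the
larva as a filled ellipse, chamber walls at a distinct intensity, and
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import ellipse as _draw_ellipse

from .core import ChamberGeometry, Trajectory
from .errors import ValidationError

__all__ = ["RenderParams", "frame_layout", "render_frames", "write_stack", "read_stack"]


@dataclass(frozen=True)
class RenderParams:
    """Rendering configuration.

    Intensities are 8-bit levels; the larva is an axis-aligned filled
    ellipse with the given semi-axes (a third-instar larva is a few mm
    long, but the centroid blob the tracker sees is smaller).
    """

    larva_semi_axis_z_mm: float = 1.0
    larva_semi_axis_x_mm: float = 0.45
    foreground: int = 200
    background: int = 40
    wall_intensity: int = 120
    wall_px: int = 2
    margin_mm: float = 1.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        for v in (self.foreground, self.background, self.wall_intensity):
            if not 0 <= v <= 255:
                raise ValidationError("intensities must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def frame_layout(
    geometry: ChamberGeometry, params: RenderParams
) -> tuple[int, int, ChamberGeometry]:
    """Frame shape and calibrated geometry for a renderer configuration.

    Returns (height_px, width_px, geometry-with-calibration).  Row 0 is
    the top of the image, ``margin_mm`` above the air-chamber top; the
    gel surface sits at ``surface_row`` with z = (surface_row - row) /
    px_per_mm.  The chamber centerline (x = 0) maps to ``center_col``.
    """
    s = geometry.px_per_mm
    height = int(round((params.margin_mm + geometry.air_top_z - geometry.gel_bottom_z + params.margin_mm) * s))
    width = int(round(geometry.chamber_width * s)) + 2 * params.wall_px
    surface_row = (params.margin_mm + geometry.air_top_z) * s
    center_col = width / 2 - 0.5
    return height, width, replace(geometry, surface_row=surface_row, center_col=center_col)


def render_frames(
    trajectory: Trajectory,
    geometry: ChamberGeometry,
    params: RenderParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, ChamberGeometry]:
    """Render one 8-bit grayscale frame per trajectory sample.

    Returns (stack, calibrated geometry).  Missing samples yield a
    background-only frame.  Raises if a position maps outside the frame.
    """
    if params is None:
        params = RenderParams()
    height, width, cal = frame_layout(geometry, params)
    rng = np.random.default_rng(seed)
    n = len(trajectory)
    stack = np.empty((n, height, width), dtype=np.uint8)

    base = np.full((height, width), params.background, dtype=float)
    base[:, : params.wall_px] = params.wall_intensity
    base[:, width - params.wall_px :] = params.wall_intensity

    rz = params.larva_semi_axis_z_mm * geometry.px_per_mm
    rx = params.larva_semi_axis_x_mm * geometry.px_per_mm
    for i in range(n):
        frame = base.copy()
        if not trajectory.missing[i]:
            row = cal.surface_row - trajectory.z[i] * geometry.px_per_mm
            col = cal.center_col + trajectory.x[i] * geometry.px_per_mm
            if not (0 <= row < height and 0 <= col < width):
                raise ValidationError(
                    f"frame {i}: position (x={trajectory.x[i]:.2f}, z={trajectory.z[i]:.2f}) "
                    "maps outside the frame"
                )
            rr, cc = _draw_ellipse(row, col, rz, rx, shape=(height, width))
            frame[rr, cc] = params.foreground
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        stack[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack, cal


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a frame stack as a multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, stack)
    return path


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
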