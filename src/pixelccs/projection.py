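"""Rotationally-averaged projected silhouette area (projection-approximation CCS).

The estimator: rotate the sphere cloud through a two-angle grid of viewing
orientations, orthographically project every sphere to a disk on the viewing
plane, rasterize the disk union at a fixed pixel size, count every
``stride``-th pixel along each axis whose center falls inside the silhouette,
and scale the count back up by ``stride**2``.  The mean over all orientations
is the collision cross section (CCS, Å²) in the projection approximation —
no buffer-gas scattering is modelled.

The strided sampling (one pixel in every *k* per axis, count multiplied by
*k²*) trades resolution for speed while remaining unbiased on average; its
coarse-graining behaviour is exposed through :func:`sweep_stride`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import SphereCloud

#: Default viewing-angle step (degrees): 36 orientations.
DEFAULT_THETA = 30.0
#: Default sampling stride (the "measure 1 in every k pixels" k).
DEFAULT_STRIDE = 20
#: Default raster resolution (Å per pixel).
DEFAULT_PIXEL_SIZE = 0.2
#: Default padding (Å) around the projected bounding box.
DEFAULT_PADDING = 2.0
#: Refuse rasters larger than this many pixels (before striding).
DEFAULT_MAX_PIXELS = 400_000_000


class RasterTooLargeError(MemoryError):
    """Raster grid exceeds the configured pixel budget."""


@dataclass(frozen=True)
class RasterConfig:
    """Resolution parameters of the area measurement.

    pixel_size : Å per pixel of the raster grid.
    stride     : sample 1 pixel in every ``stride`` along x and y; the pixel
                 count is multiplied by ``stride**2`` afterwards.
    padding    : Å added on every side of the projected bounding box so the
                 silhouette never clips.
    """

    pixel_size: float = DEFAULT_PIXEL_SIZE
    stride: int = DEFAULT_STRIDE
    padding: float = DEFAULT_PADDING
    max_pixels: int = DEFAULT_MAX_PIXELS

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if int(self.stride) != self.stride or self.stride < 1:
            raise ValueError(f"stride must be an integer >= 1, got {self.stride}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")


@dataclass(frozen=True)
class RotationGrid:
    """The set of viewing orientations generated by an angular step theta.

    Orientations are all pairs ``(i*theta, j*theta)`` of rotations about the
    fixed laboratory x- then y-axis, for i, j in ``[0, 180/theta)`` — a
    ``(180/theta)**2``-point grid.  ``180/theta`` must be an integer; a
    requested step for which it is not is replaced by the admissible step
    closest to it (``theta_effective``), ties resolved toward the smaller
    step.
    """

    theta_requested: float
    theta_effective: float
    orientations: tuple[tuple[float, float], ...]

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)


def make_rotation_grid(theta: float) -> RotationGrid:
    """Build the orientation grid for an angular step of ``theta`` degrees.

    Admissible steps are 180/n for integer n >= 1, so the endpoints are one
    orientation at theta=180 and 32,400 at theta=1.
    """
    if not 0 < theta <= 180:
        raise ValueError(f"theta must be in (0, 180], got {theta}")
    n_exact = 180.0 / theta
    candidates = {max(1, int(np.floor(n_exact))), int(np.ceil(n_exact))}
    # smaller angle = larger n; ties resolved toward the smaller angle
    n = min(candidates, key=lambda k: (abs(180.0 / k - theta), 180.0 / k))
    theta_eff = 180.0 / n
    orientations = tuple(
        (i * theta_eff, j * theta_eff) for i in range(n) for j in range(n)
    )
    return RotationGrid(theta, theta_eff, orientations)


@dataclass
class ProjectionResult:
    """Per-orientation silhouette areas and their mean (the CCS estimate)."""

    areas: np.ndarray  # Å², one per orientation
    grid: RotationGrid
    raster: RasterConfig
    n_spheres: int
    source_id: str = ""

    @property
    def ccs(self) -> float:
        """Mean projected area over all viewing orientations (Å²)."""
        return float(np.mean(self.areas))

    def to_dict(self) -> dict:
        return {
            "ccs_A2": self.ccs,
            "n_orientations": self.grid.n_orientations,
            "theta_requested_deg": self.grid.theta_requested,
            "theta_effective_deg": self.grid.theta_effective,
            "pixel_size_A": self.raster.pixel_size,
            "stride": self.raster.stride,
            "padding_A": self.raster.padding,
            "n_spheres": self.n_spheres,
            "source": self.source_id,
            "area_min_A2": float(np.min(self.areas)),
            "area_max_A2": float(np.max(self.areas)),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path) -> None:
        lines = ["alpha_deg,beta_deg,area_A2"]
        for (a, b), area in zip(self.grid.orientations, self.areas):
            lines.append(f"{a:g},{b:g},{area:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SweepResult:
    """CCS (and wall time) as one raster/grid parameter is varied."""

    parameter: str
    values: list[float]
    ccs: list[float]
    elapsed_s: list[float]

    def write_csv(self, path: str | Path) -> None:
        lines = [f"{self.parameter},ccs_A2,elapsed_s"]
        for v, c, t in zip(self.values, self.ccs, self.elapsed_s):
            lines.append(f"{v:g},{c:.6f},{t:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def rotation_matrix(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Rotation about the lab x-axis by alpha, then the lab y-axis by beta."""
    a = np.deg2rad(alpha_deg)
    b = np.deg2rad(beta_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(a), -np.sin(a)],
                   [0, np.sin(a), np.cos(a)]])
    ry = np.array([[np.cos(b), 0, np.sin(b)],
                   [0, 1, 0],
                   [-np.sin(b), 0, np.cos(b)]])
    return ry @ rx


def stride_corrected_count(sampled_count: int, stride: int) -> int:
    """Scale a strided pixel count back to the full grid: count × stride²."""
    if sampled_count < 0:
        raise ValueError("sampled_count must be >= 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return int(sampled_count) * int(stride) ** 2

def pixels_per_angstrom(window_pixels: float, window_angstroms: float) -> float:
    """Pixels per Å of a viewer window; its inverse is a RasterConfig pixel_size."""
    if window_pixels <= 0 or window_angstroms <= 0:
        raise ValueError("window size must be positive in both units")
    return window_pixels / window_angstroms


def _projected_disks(cloud: SphereCloud,
                     orientation: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the cloud and drop the viewing (z) axis: disk centers + radii."""
    rot = rotation_matrix(*orientation)
    xy = cloud.centers @ rot.T[:, :2]
    return xy, cloud.radii


def _raster_axes(xy: np.ndarray, radii: np.ndarray,
                 raster: RasterConfig) -> tuple[np.ndarray, np.ndarray]:
    """Strided pixel-center coordinates of the padded bounding-box raster.

    The grid anchors at the padded box's lower-left corner; strided sampling
    starts at pixel (0, 0).  Pixel centers sit at (index + 0.5) * pixel_size.
    """
    lo = (xy - radii[:, None]).min(axis=0) - raster.padding
    hi = (xy + radii[:, None]).max(axis=0) + raster.padding
    px = raster.pixel_size
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / px)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / px)))
    if nx * ny > raster.max_pixels:
        raise RasterTooLargeError(
            f"raster of {nx}x{ny} pixels exceeds max_pixels="
            f"{raster.max_pixels}; increase pixel_size or max_pixels")
    xs = lo[0] + (np.arange(0, nx, raster.stride) + 0.5) * px
    ys = lo[1] + (np.arange(0, ny, raster.stride) + 0.5) * px
    return xs, ys


def project_silhouette(cloud: SphereCloud, orientation: tuple[float, float],
                       raster: RasterConfig | None = None) -> float:
    """Strided rasterized silhouette area (Å²) of one viewing orientation.

    A sampled pixel counts when its center lies inside at least one projected
    disk; the count is multiplied by stride² and by pixel_size² to give Å².
    Deterministic for fixed inputs.
    """
    raster = raster or RasterConfig()
    xy, radii = _projected_disks(cloud, orientation)
    xs, ys = _raster_axes(xy, radii, raster)
    mask = np.zeros((xs.size, ys.size), dtype=bool)
    r2 = radii ** 2
    for k in range(len(radii)):
        cx, cy = xy[k]
        r = radii[k]
        i0, i1 = np.searchsorted(xs, (cx - r, cx + r))
        j0, j1 = np.searchsorted(ys, (cy - r, cy + r))
        if i0 >= i1 or j0 >= j1:
            continue
        sub = mask[i0:i1, j0:j1]
        dx2 = (xs[i0:i1, None] - cx) ** 2
        dy2 = (ys[None, j0:j1] - cy) ** 2
        sub |= dx2 + dy2 <= r2[k]
    sampled = int(np.count_nonzero(mask))
    return stride_corrected_count(sampled, raster.stride) * raster.pixel_size ** 2


def predict_ccs(cloud: SphereCloud, theta: float = DEFAULT_THETA,
                raster: RasterConfig | None = None) -> ProjectionResult:
    """CCS of a sphere cloud: mean silhouette area over the rotation grid.

    Defaults (theta = 30°, stride = 20, pixel_size = 0.2 Å, probe already
    baked into the cloud) are the operating point of the method; all are
    overridable.
    """
    raster = raster or RasterConfig()
    grid = make_rotation_grid(theta)
    cloud = cloud.centered()
    areas = np.array([project_silhouette(cloud, o, raster)
                      for o in grid.orientations])
    return ProjectionResult(areas=areas, grid=grid, raster=raster,
                            n_spheres=cloud.n_spheres, source_id=cloud.source_id)


def sweep_stride(cloud: SphereCloud, theta: float,
                 strides: Sequence[int],
                 raster: RasterConfig | None = None) -> SweepResult:
    """CCS versus sampling stride at fixed theta (coarse-graining behaviour).

    The raster geometry (pixel size, padding) is shared across strides so
    only the sampling density changes.
    """
    if not strides:
        raise ValueError("strides must be non-empty")
    base = raster or RasterConfig()
    values, ccs, elapsed = [], [], []
    for k in sorted(set(int(s) for s in strides)):
        if k < 1:
            raise ValueError(f"stride must be >= 1, got {k}")
        cfg = RasterConfig(pixel_size=base.pixel_size, stride=k,
                           padding=base.padding, max_pixels=base.max_pixels)
        t0 = time.perf_counter()
        res = predict_ccs(cloud, theta, cfg)
        elapsed.append(time.perf_counter() - t0)
        values.append(float(k))
        ccs.append(res.ccs)
    return SweepResult("stride", values, ccs, elapsed)


def sweep_theta(cloud: SphereCloud, thetas: Sequence[float],
                raster: RasterConfig | None = None) -> SweepResult:
    """CCS versus angular step (number of viewing orientations)."""
    if len(thetas) == 0:
        raise ValueError("thetas must be non-empty")
    raster = raster or RasterConfig()
    values, ccs, elapsed = [], [], []
    for theta in sorted(set(float(t) for t in thetas)):
        t0 = time.perf_counter()
        res = predict_ccs(cloud, theta, raster)
        elapsed.append(time.perf_counter() - t0)
        values.append(theta)
        ccs.append(res.ccs)
    return SweepResult("theta", values, ccs, elapsed)
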