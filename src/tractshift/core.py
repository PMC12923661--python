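"""Shared spatial conventions and acquisition containers.

Conventions used throughout the package:

* voxel indices are 0-based, axis order (x, y, z) with z the feet-head axis;
* world coordinates are in mm, voxel-center convention:
  ``world = (index + 0.5) * voxel_size``;
* all grids are isotropic (single scalar voxel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "AcquisitionScheme", "PeakVolume", "default_scheme"]


@dataclass(frozen=True)
class Grid:
    """Isotropic voxel grid with a voxel-center world mapping."""

    shape: tuple[int, int, int]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> world-mm affine (RAS-like, voxel-center)."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.voxel_size_mm / 2.0
        return aff

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_size_mm

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return (idx + 0.5) * self.voxel_size_mm

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Containing voxel index of each mm point (no clipping)."""
        return np.floor(np.asarray(points) / self.voxel_size_mm).astype(np.int64)

    def inside(self, voxels: np.ndarray) -> np.ndarray:
        v = np.asarray(voxels)
        return np.all((v >= 0) & (v < np.asarray(self.shape)), axis=-1)


def _spiral_directions(n: int, offset: float = 0.5) -> np.ndarray:
    """Deterministic, well-spread unit vectors (generalized spiral on the sphere)."""
    i = np.arange(n) + offset
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    d = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Two-shell diffusion scheme: b-values in s/mm^2 and unit gradient directions.

    The default scheme mirrors a 9-minute intraoperative protocol: six b=0
    volumes, 20 directions at b=1000 and 32 at b=2000 s/mm^2, 2.55 mm
    isotropic voxels.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: float = 2.55
    grid_shape: tuple[int, int, int] = (24, 24, 32)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit-norm")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.grid_shape), self.voxel_size_mm)


def default_scheme(
    grid_shape: tuple[int, int, int] = (24, 24, 32), voxel_size_mm: float = 2.55
) -> AcquisitionScheme:
    """Six b0, 20 x b=1000, 32 x b=2000; deterministic spread directions."""
    bvals = np.concatenate([np.zeros(6), np.full(20, 1000.0), np.full(32, 2000.0)])
    bvecs = np.concatenate(
        [np.zeros((6, 3)), _spiral_directions(20), _spiral_directions(32, offset=0.7)]
    )
    return AcquisitionScheme(bvals, bvecs, voxel_size_mm, tuple(grid_shape))


@dataclass
class PeakVolume:
    """Discrete per-voxel fiber peaks: unit directions with amplitudes.

    Directions are sign-ambiguous (d and -d are the same fiber). Amplitude 0
    marks an empty slot; the tracker treats amplitudes below its floor as
    background.
    """

    dirs: np.ndarray  # (X, Y, Z, K, 3)
    amps: np.ndarray  # (X, Y, Z, K)
    grid: Grid
    max_peaks: int = field(init=False)

    def __post_init__(self) -> None:
        if self.dirs.shape[:3] != tuple(self.grid.shape) or self.dirs.shape[-1] != 3:
            raise ValueError("dirs must have shape grid + (K, 3)")
        if self.amps.shape != self.dirs.shape[:4]:
            raise ValueError("amps must have shape grid + (K,)")
        if np.any(self.amps < 0):
            raise ValueError("amplitudes must be non-negative")
        self.max_peaks = self.dirs.shape[3]

    @classmethod
    def empty(cls, grid: Grid, max_peaks: int = 3) -> "PeakVolume":
        shp = tuple(grid.shape)
        return cls(
            dirs=np.zeros(shp + (max_peaks, 3), dtype=np.float64),
            amps=np.zeros(shp + (max_peaks,), dtype=np.float64),
            grid=grid,
        )

    def add_peaks(self, mask: np.ndarray, directions: np.ndarray, amplitude: float) -> None:
        """Insert one peak per masked voxel into the first free slot."""
        idx = np.argwhere(mask)
        directions = np.asarray(directions, dtype=float)
        if directions.shape != (idx.shape[0], 3):
            raise ValueError("one direction per masked voxel required")
        norms = np.linalg.norm(directions, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length peak direction")
        directions = directions / norms[:, None]
        amps_here = self.amps[idx[:, 0], idx[:, 1], idx[:, 2]]  # (n, K)
        slot = np.argmin(amps_here > 0, axis=1)  # first zero slot
        if np.any(amps_here[np.arange(len(idx)), slot] > 0):
            raise ValueError("no free peak slot in some voxels")
        self.amps[idx[:, 0], idx[:, 1], idx[:, 2], slot] = amplitude
        self.dirs[idx[:, 0], idx[:, 1], idx[:, 2], slot] = directions

    def mirrored(self, axis: int = 0) -> "PeakVolume":
        """Peak field reflected about the grid center along one axis."""
        dirs = np.flip(self.dirs, axis=axis).copy()
        amps = np.flip(self.amps, axis=axis).copy()
        dirs[..., axis] *= -1
        return PeakVolume(dirs=dirs, amps=amps, grid=self.grid)
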