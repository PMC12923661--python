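"""Macro- and microstructural tract metrics.

Macrostructure: tract volume is the count of voxels containing at least one
streamline vertex times the voxel volume, reported both raw and as a
percentage of the supratentorial white-matter volume; the effective tract
diameter models the tract as a cylinder,

    diameter = 2 * sqrt(volume / (pi * length)),

with length the mean streamline length.

Microstructure: whole-tract FA/MD are two-stage means — the scalar map is
sampled at each vertex (nearest voxel), averaged within each streamline,
then averaged unweighted across streamlines. Along-tract profiles resample
every streamline to ``n_segments`` equal-arc-length segments of the mean
centerline and average the map over the vertices assigned (nearest segment
midpoint) to each segment. The default of 55 segments follows the ceiling
of mean tract length (~138 mm) over the voxel size (2.55 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Grid
from .tracking import StreamlineSet

__all__ = [
    "Centerline",
    "TractProfile",
    "default_n_segments",
    "tract_volume",
    "diameter",
    "whole_tract_stat",
    "resample_streamline",
    "centerline",
    "along_tract_profile",
    "compute_profile",
]


def default_n_segments(mean_length_mm: float, voxel_size_mm: float) -> int:
    """Number of along-tract segments: ceil(mean length / voxel size)."""
    if mean_length_mm <= 0 or voxel_size_mm <= 0:
        raise ValueError("lengths must be positive")
    return math.ceil(mean_length_mm / voxel_size_mm)


def tract_volume(
    streamlines: StreamlineSet, grid: Grid, supratentorial_wm_mask: np.ndarray
) -> tuple[float, float]:
    """(volume in mm^3, volume as % of supratentorial WM volume)."""
    wm = np.asarray(supratentorial_wm_mask, dtype=bool)
    if not wm.any():
        raise ValueError("empty white-matter mask")
    if len(streamlines) == 0:
        raise ValueError("empty streamline set")
    _, _, vox, inside = streamlines.vertex_voxels(grid)
    flat = np.ravel_multi_index(tuple(vox[inside].T), grid.shape)
    n_vox = np.unique(flat).size
    volume = n_vox * grid.voxel_volume_mm3
    wm_volume = int(wm.sum()) * grid.voxel_volume_mm3
    return float(volume), float(100.0 * volume / wm_volume)


def diameter(volume_mm3: float, length_mm: float) -> float:
    """Cylinder-equivalent tract diameter in mm."""
    if volume_mm3 <= 0 or length_mm <= 0:
        raise ValueError("volume and length must be positive")
    return float(2.0 * np.sqrt(volume_mm3 / (np.pi * length_mm)))


def _sample_map(points: np.ndarray, scalar_map: np.ndarray, grid: Grid) -> np.ndarray:
    """Nearest-voxel map values at mm points; NaN outside the grid."""
    vox = grid.world_to_voxel(points)
    ok = grid.inside(vox)
    out = np.full(points.shape[0], np.nan)
    out[ok] = scalar_map[tuple(vox[ok].T)]
    return out


def whole_tract_stat(
    streamlines: StreamlineSet, scalar_map: np.ndarray, grid: Grid
) -> tuple[float, int]:
    """Across-streamline mean of per-streamline vertex means.

    Each streamline contributes equally regardless of vertex count.
    Streamlines with no valid (in-grid, non-NaN) sample are excluded; their
    count is returned alongside.
    """
    n = len(streamlines)
    ids, _, vox, inside = streamlines.vertex_voxels(grid)
    vals = np.full(ids.shape[0], np.nan)
    vals[inside] = scalar_map[tuple(vox[inside].T)]
    ok = np.isfinite(vals)
    cnt = np.bincount(ids[ok], minlength=n)
    sums = np.bincount(ids[ok], weights=vals[ok], minlength=n)
    has = cnt > 0
    n_excluded = int(n - has.sum())
    if not has.any():
        raise ValueError("no streamline overlaps the scalar map's valid voxels")
    return float(np.mean(sums[has] / cnt[has])), n_excluded


def resample_streamline(s: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to n_points equidistant-in-arc-length points."""
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return np.repeat(s[:1], n_points, axis=0)
    t = np.linspace(0.0, arc[-1], n_points)
    return np.stack([np.interp(t, arc, s[:, c]) for c in range(3)], axis=1)


@dataclass
class Centerline:
    """Mean tract centerline with equal-arc-length segment boundaries.

    Orientation follows the gated streamlines (dentate -> motor cortex for
    the DRTT, Wernicke -> Broca for the AF), so segment 1 sits at the
    dentate (or Wernicke) end.
    """

    points: np.ndarray  # (n_segments + 1, 3)

    @property
    def n_segments(self) -> int:
        return self.points.shape[0] - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.points[:-1] + self.points[1:])


def resample_all(streamlines: StreamlineSet, n_points: int) -> np.ndarray:
    """All streamlines resampled to n_points each, shape (n, n_points, 3).

    Uses a vectorized path when vertex spacing is uniform within each
    streamline (true of fixed-step tracking output); falls back to per-line
    arc-length interpolation otherwise.
    """
    n = len(streamlines)
    lens = np.array([s.shape[0] for s in streamlines])
    if (lens < 2).any():
        return np.stack([resample_streamline(s, n_points) for s in streamlines])
    lmax = int(lens.max())
    pad = np.zeros((n, lmax, 3))
    for i, s in enumerate(streamlines):
        pad[i, : lens[i]] = s
        pad[i, lens[i] :] = s[-1]
    seg = np.linalg.norm(np.diff(pad, axis=1), axis=2)
    valid = np.arange(lmax - 1)[None, :] < (lens - 1)[:, None]
    step = seg[:, 0]
    uniform = np.all(np.abs(seg[valid] - np.repeat(step, lens - 1)) < 1e-6)
    if not uniform:
        return np.stack([resample_streamline(s, n_points) for s in streamlines])
    t = np.linspace(0.0, 1.0, n_points)[None, :] * (lens - 1)[:, None]
    i0 = np.clip(np.floor(t).astype(np.int64), 0, (lens - 2)[:, None])
    w = (t - i0)[..., None]
    rows = np.arange(n)[:, None]
    return pad[rows, i0] * (1 - w) + pad[rows, i0 + 1] * w


def centerline(streamlines: StreamlineSet, n_segments: int = 55) -> Centerline:
    """Pointwise mean of all streamlines resampled to n_segments + 1 points."""
    if len(streamlines) == 0:
        raise ValueError("cannot build a centerline from an empty set")
    return Centerline(points=resample_all(streamlines, n_segments + 1).mean(axis=0))


def segment_assignment(
    streamlines: StreamlineSet, cline: Centerline, grid: Grid
) -> np.ndarray:
    """Nearest-midpoint segment index of every vertex (ties to lower index)."""
    _, verts, _, _ = streamlines.vertex_voxels(grid)
    if verts.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    return np.argmin(cdist(verts, cline.midpoints), axis=1)


def along_tract_profile(
    streamlines: StreamlineSet,
    scalar_map: np.ndarray,
    cline: Centerline,
    grid: Grid,
    assignment: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment means of the map over vertices projected to the centerline.

    Every vertex of every streamline is assigned to the nearest (Euclidean)
    segment midpoint, ties to the lower index; a precomputed ``assignment``
    (from :func:`segment_assignment`) may be supplied when profiling several
    maps over the same tract. Returns (profile, counts); empty segments
    carry NaN with count 0.
    """
    n_seg = cline.n_segments
    _, verts, vox, inside = streamlines.vertex_voxels(grid)
    vals = np.full(verts.shape[0], np.nan)
    vals[inside] = scalar_map[tuple(vox[inside].T)]
    if assignment is None:
        assignment = segment_assignment(streamlines, cline, grid)
    ok = np.isfinite(vals)
    profile = np.full(n_seg, np.nan)
    counts = np.zeros(n_seg, dtype=np.int64)
    if ok.any():
        seg = assignment[ok]
        counts = np.bincount(seg, minlength=n_seg)
        sums = np.bincount(seg, weights=vals[ok], minlength=n_seg)
        nz = counts > 0
        profile[nz] = sums[nz] / counts[nz]
    return profile, counts


@dataclass
class TractProfile:
    """Macro + micro metrics for one tract at one timepoint."""

    tract: str
    side: str
    timepoint: str
    volume_mm3: float
    volume_norm: float  # % of supratentorial WM volume
    length_mm: float  # mean streamline length
    diameter_mm: float
    fa_mean: float
    md_mean: float
    fa_profile: np.ndarray
    md_profile: np.ndarray
    segment_counts: np.ndarray
    n_streamlines: int


def compute_profile(
    streamlines: StreamlineSet,
    fa_map: np.ndarray,
    md_map: np.ndarray,
    grid: Grid,
    supratentorial_wm_mask: np.ndarray,
    tract: str,
    side: str,
    timepoint: str,
    n_segments: int = 55,
) -> TractProfile:
    """Full tractometry record for a gated, oriented streamline set."""
    vol, vol_norm = tract_volume(streamlines, grid, supratentorial_wm_mask)
    length = float(streamlines.lengths_mm.mean())
    cl = centerline(streamlines, n_segments)
    assign = segment_assignment(streamlines, cl, grid)
    fa_prof, counts = along_tract_profile(streamlines, fa_map, cl, grid, assign)
    md_prof, _ = along_tract_profile(streamlines, md_map, cl, grid, assign)
    fa_mean, _ = whole_tract_stat(streamlines, fa_map, grid)
    md_mean, _ = whole_tract_stat(streamlines, md_map, grid)
    return TractProfile(
        tract=tract,
        side=side,
        timepoint=timepoint,
        volume_mm3=vol,
        volume_norm=vol_norm,
        length_mm=length,
        diameter_mm=diameter(vol, length),
        fa_mean=fa_mean,
        md_mean=md_mean,
        fa_profile=fa_prof,
        md_profile=md_prof,
        segment_counts=counts,
        n_streamlines=len(streamlines),
    )
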