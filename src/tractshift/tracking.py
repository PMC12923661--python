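"""Deterministic FACT streamline propagation over a discrete peak field.

FACT (fiber assignment by continuous tracking) advances with the fiber
direction of the *current voxel* — no interpolation — in fixed 1-mm steps
from a dense seed lattice. Propagation is bidirectional from each seed and
terminates when

* the best-aligned peak of the voxel being entered has amplitude below the
  floor (default 0.01),
* the turn angle between successive step directions exceeds the threshold
  (default 60 degrees), or
* the position leaves the white-matter mask (gray-white interface rule; the
  exiting vertex is retained).

Peaks are sign-ambiguous; at every step the candidate direction is flipped
into the hemisphere of the incoming direction before the angle test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Grid, PeakVolume

__all__ = ["TrackingParams", "StreamlineSet", "seed_grid", "track"]


@dataclass(frozen=True)
class TrackingParams:
    step_mm: float = 1.0
    seed_spacing_mm: float = 1.0
    amp_floor: float = 0.01
    max_turn_deg: float = 60.0
    min_length_mm: float = 2.0  # two steps; drops degenerate seeds
    max_steps: int = 1000

    def __post_init__(self) -> None:
        if min(self.step_mm, self.seed_spacing_mm, self.min_length_mm) <= 0:
            raise ValueError("step, seed spacing and min length must be positive")
        if self.amp_floor < 0 or self.max_steps <= 0:
            raise ValueError("amp_floor must be >= 0 and max_steps positive")
        if not 0 < self.max_turn_deg <= 90:
            raise ValueError("max_turn_deg must lie in (0, 90]")


@dataclass
class StreamlineSet:
    """Ordered 3D polylines in mm space with provenance metadata."""

    streamlines: list[np.ndarray]
    meta: dict = field(default_factory=dict)
    n_skipped_seeds: int = 0

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def lengths_mm(self) -> np.ndarray:
        cached = getattr(self, "_lengths", None)
        if cached is None:
            if not self.streamlines:
                cached = np.empty(0)
            else:
                lens = np.array([s.shape[0] for s in self.streamlines], dtype=np.int64)
                verts = np.vstack(self.streamlines)
                seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
                starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
                # zero the junction diffs between consecutive streamlines
                seg[starts[1:] - 1] = 0.0
                cached = np.add.reduceat(np.concatenate([seg, [0.0]]), starts)
                cached[lens == 1] = 0.0
            self._lengths = cached
        return cached

    def subset(self, indices) -> "StreamlineSet":
        return StreamlineSet(
            [self.streamlines[i] for i in indices], dict(self.meta), self.n_skipped_seeds
        )

    def vertex_voxels(self, grid) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(streamline ids, vertices, voxel indices, in-grid flags) of all
        vertices, concatenated in order; cached per grid."""
        key = (tuple(grid.shape), grid.voxel_size_mm)
        cache = getattr(self, "_vox_cache", None)
        if cache is None or cache[0] != key:
            lens = np.array([s.shape[0] for s in self.streamlines], dtype=np.int64)
            ids = np.repeat(np.arange(len(self.streamlines)), lens)
            verts = (
                np.vstack(self.streamlines) if self.streamlines else np.empty((0, 3))
            )
            vox = grid.world_to_voxel(verts)
            inside = grid.inside(vox)
            cache = (key, (ids, verts, vox, inside))
            self._vox_cache = cache
        return cache[1]


def seed_grid(mask: np.ndarray, grid: Grid, spacing_mm: float = 1.0) -> np.ndarray:
    """Seed lattice at the given spacing over the mask's bounding box.

    The lattice origin sits at the lower corner of the in-mask bounding box;
    points whose containing voxel is outside the mask are discarded. Order is
    lexicographic in (x, y, z), hence deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3))
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) * grid.voxel_size_mm
    hi = (idx.max(axis=0) + 1) * grid.voxel_size_mm
    axes = [lo[a] + spacing_mm * np.arange(int((hi[a] - lo[a]) / spacing_mm) + 1) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vox = grid.world_to_voxel(pts)
    ok = grid.inside(vox)
    ok[ok] &= mask[tuple(vox[ok].T)]
    return pts[ok]


def _half_tracks(
    peaks: PeakVolume,
    wm_mask: np.ndarray,
    pos0: np.ndarray,
    u0: np.ndarray,
    params: TrackingParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one half-track per row of (pos0, u0); vectorized over tracks.

    Returns (vertices (n, max_steps, 3), counts (n,)): vertices appended
    after the seed, in step order.
    """
    grid = peaks.grid
    vs = grid.voxel_size_mm
    n = pos0.shape[0]
    cap = min(params.max_steps, 64)  # grown on demand
    verts = np.full((n, cap, 3), np.nan)
    counts = np.zeros(n, dtype=np.int64)
    pos = pos0.astype(float).copy()
    u = u0.astype(float).copy()
    active = np.ones(n, dtype=bool)
    cos_floor = np.cos(np.radians(params.max_turn_deg))
    shape = np.asarray(grid.shape)
    amp_max = peaks.amps.max(axis=3)

    for step_i in range(params.max_steps):
        ai = np.flatnonzero(active)
        if ai.size == 0:
            break
        if step_i >= cap:
            grow = min(max(cap, 64), params.max_steps - cap)
            verts = np.concatenate([verts, np.full((n, grow, 3), np.nan)], axis=1)
            cap += grow
        v = np.floor(pos[ai] / vs).astype(np.int64)
        d_all = peaks.dirs[v[:, 0], v[:, 1], v[:, 2]]  # (a, K, 3)
        a_all = peaks.amps[v[:, 0], v[:, 1], v[:, 2]]  # (a, K)
        dots = np.einsum("akc,ac->ak", d_all, u[ai])
        score = np.where(a_all > 0, np.abs(dots), -1.0)
        j = np.argmax(score, axis=1)
        r = np.arange(ai.size)
        cos_t = np.abs(dots[r, j])
        # turn-angle rule (amplitude of the current voxel was vetted on entry)
        go = (score[r, j] >= 0) & (cos_t >= cos_floor)
        sign = np.where(dots[r, j] < 0, -1.0, 1.0)
        d = d_all[r, j] * sign[:, None]
        new_pos = pos[ai] + params.step_mm * d

        v_new = np.floor(new_pos / vs).astype(np.int64)
        inside = np.all((v_new >= 0) & (v_new < shape), axis=1)
        in_wm = np.zeros(ai.size, dtype=bool)
        in_wm[inside] = wm_mask[tuple(v_new[inside].T)]
        amp_ok = np.zeros(ai.size, dtype=bool)
        amp_ok[inside] = amp_max[tuple(v_new[inside].T)] >= params.amp_floor

        # exiting white matter: retain the terminal vertex, then stop
        append = go & (~in_wm | amp_ok)
        cont = go & in_wm & amp_ok
        ap = ai[append]
        verts[ap, counts[ap]] = new_pos[append]
        counts[ap] += 1
        pos[ai[cont]] = new_pos[cont]
        u[ai[cont]] = d[cont]
        active[ai] = cont
    return verts, counts


def track(
    peaks: PeakVolume,
    params: TrackingParams,
    wm_mask: np.ndarray,
    seeds: np.ndarray,
    meta: dict | None = None,
    batch_size: int = 8192,
) -> StreamlineSet:
    """Bidirectional FACT propagation from every seed.

    Seeds outside the white-matter mask (or the grid) are skipped and
    counted. The first-step direction is the seed voxel's largest-amplitude
    peak, propagated in both signs; the two half-tracks are joined at the
    seed. Tracks shorter than ``min_length_mm`` are dropped.
    """
    grid = peaks.grid
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if tuple(wm_mask.shape) != tuple(grid.shape):
        raise ValueError("white-matter mask and peak field must share the grid")
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)

    vox = grid.world_to_voxel(seeds)
    ok = grid.inside(vox)
    ok[ok] &= wm_mask[tuple(vox[ok].T)]
    n_skipped = int((~ok).sum())
    seeds = seeds[ok]
    vox = vox[ok]

    streamlines: list[np.ndarray] = []
    min_verts = int(np.ceil(params.min_length_mm / params.step_mm)) + 1
    for start in range(0, seeds.shape[0], batch_size):
        s = seeds[start : start + batch_size]
        v = vox[start : start + batch_size]
        amps = peaks.amps[v[:, 0], v[:, 1], v[:, 2]]  # (m, K)
        top = np.argmax(amps, axis=1)
        m = np.arange(s.shape[0])
        live = amps[m, top] >= params.amp_floor
        if not live.any():
            continue
        d0 = peaks.dirs[v[live, 0], v[live, 1], v[live, 2], top[live]]
        s_live = s[live]
        fwd_v, fwd_n = _half_tracks(peaks, wm_mask, s_live, d0, params)
        bwd_v, bwd_n = _half_tracks(peaks, wm_mask, s_live, -d0, params)
        tot = bwd_n + 1 + fwd_n
        for i in np.flatnonzero(tot >= min_verts):
            line = np.empty((tot[i], 3))
            bn = bwd_n[i]
            line[:bn] = bwd_v[i, :bn][::-1]
            line[bn] = s_live[i]
            line[bn + 1 :] = fwd_v[i, : fwd_n[i]]
            streamlines.append(line)
    return StreamlineSet(streamlines, meta or {}, n_skipped_seeds=n_skipped)
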