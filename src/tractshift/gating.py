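"""Tract segmentation from whole-brain streamlines via ROI waypoint logic.

A streamline passes a gate when at least one of its vertices falls inside
every inclusion (AND) mask and none falls inside any exclusion (NOT) mask.
Membership is a vertex test — the containing voxel of a vertex — which is
adequate at 1-mm steps on 2.55-mm voxels.

Also here: the decussating vs non-decussating split of the
dentato-rubro-thalamic tract (d-DRTT ends in the motor cortex contralateral
to its dentate nucleus; side labels follow the dentate hemisphere), and the
cohort-level arcuate-fasciculus length filter (streamlines shorter than the
first percentile of the brain-height-normalized median AF length are
removed as spurious).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Grid
from .tracking import StreamlineSet

__all__ = ["GateSpec", "apply_gates", "classify_drtt", "filter_af", "brain_height_mm"]


@dataclass
class GateSpec:
    """Inclusion/exclusion waypoint masks plus optional endpoint orientation."""

    include: dict[str, np.ndarray]
    exclude: dict[str, np.ndarray] = field(default_factory=dict)
    endpoint_rois: tuple[str, str] | None = None  # keys into include
    side: str | None = None

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError("at least one inclusion ROI is required")
        overlap = set(self.include) & set(self.exclude)
        if overlap:
            raise ValueError(f"ROIs cannot be both include and exclude: {overlap}")
        if self.endpoint_rois is not None:
            for k in self.endpoint_rois:
                if k not in self.include:
                    raise ValueError(f"endpoint ROI {k!r} must be an inclusion ROI")


def _per_line_visits(
    streamlines: StreamlineSet, mask: np.ndarray, grid: Grid, ids: np.ndarray, vox: np.ndarray,
    inside: np.ndarray,
) -> np.ndarray:
    """Boolean per streamline: does any vertex's voxel fall in the mask."""
    n = len(streamlines)
    member = np.zeros(vox.shape[0], dtype=bool)
    member[inside] = mask[tuple(vox[inside].T)]
    return np.bincount(ids[member], minlength=n) > 0


def apply_gates(streamlines: StreamlineSet, gate: GateSpec, grid: Grid) -> StreamlineSet:
    """Keep streamlines crossing every include mask and no exclude mask.

    Kept streamlines are reoriented so vertex 0 is nearest the first
    endpoint ROI. An empty result is returned as such with a
    ``reconstruction_failed`` flag in the metadata (failed reconstructions
    are a real occurrence and must be accounted, not raised).
    """
    n = len(streamlines)
    if n:
        ids, _, vox, inside = streamlines.vertex_voxels(grid)
        keep = np.ones(n, dtype=bool)
        for m in gate.include.values():
            keep &= _per_line_visits(streamlines, m, grid, ids, vox, inside)
        for m in gate.exclude.values():
            keep &= ~_per_line_visits(streamlines, m, grid, ids, vox, inside)
        kept = [streamlines.streamlines[i] for i in np.flatnonzero(keep)]
    else:
        kept = []
    if gate.endpoint_rois is not None and kept:
        from scipy.spatial import cKDTree

        first_roi = gate.include[gate.endpoint_rois[0]]
        centers = grid.voxel_centers(first_roi)
        if centers.shape[0]:
            tree = cKDTree(centers)
            d_head = tree.query(np.array([s[0] for s in kept]))[0]
            d_tail = tree.query(np.array([s[-1] for s in kept]))[0]
            kept = [
                s if dh <= dt else s[::-1].copy()
                for s, dh, dt in zip(kept, d_head, d_tail)
            ]
    meta = dict(streamlines.meta)
    meta["gate_side"] = gate.side
    meta["reconstruction_failed"] = len(kept) == 0
    return StreamlineSet(kept, meta, streamlines.n_skipped_seeds)


def classify_drtt(
    streamlines: StreamlineSet,
    dentate_side: str,
    motor_masks: dict[str, np.ndarray],
    grid: Grid,
) -> dict[str, StreamlineSet]:
    """Split dentate- and motor-gated DRTT streamlines into d- and nd-DRTT.

    The motor-end vertex (the last vertex after orientation, dentate first)
    decides: contralateral motor cortex -> d_DRTT, ipsilateral -> nd_DRTT,
    neither -> unclassified. The side label of both components is the
    dentate hemisphere.
    """
    if dentate_side not in ("left", "right"):
        raise ValueError("dentate_side must be 'left' or 'right'")
    contra = "right" if dentate_side == "left" else "left"
    out: dict[str, list] = {"d_DRTT": [], "nd_DRTT": [], "unclassified": []}
    if len(streamlines):
        ends = np.array([s[-1] for s in streamlines])
        vox = grid.world_to_voxel(ends)
        inside = grid.inside(vox)
        # a terminal vertex may sit just outside the grid; fall back one step
        for i, s in enumerate(streamlines):
            if not inside[i] and s.shape[0] > 1:
                vox[i] = grid.world_to_voxel(s[-2:-1])[0]
                inside[i] = grid.inside(vox[i : i + 1])[0]
        for i, s in enumerate(streamlines):
            tup = tuple(vox[i])
            if inside[i] and motor_masks[contra][tup]:
                out["d_DRTT"].append(s)
            elif inside[i] and motor_masks[dentate_side][tup]:
                out["nd_DRTT"].append(s)
            else:
                out["unclassified"].append(s)
    meta = dict(streamlines.meta)
    meta["side"] = dentate_side
    return {k: StreamlineSet(v, dict(meta)) for k, v in out.items()}


def brain_height_mm(brain_mask: np.ndarray, grid: Grid) -> float:
    """Feet-head (z) extent of the brain mask, in mm — a proxy of brain size."""
    zs = np.flatnonzero(brain_mask.any(axis=(0, 1)))
    if zs.size == 0:
        raise ValueError("empty brain mask")
    return float((zs[-1] - zs[0] + 1) * grid.voxel_size_mm)


def filter_af(
    af_sets: dict[str, StreamlineSet],
    brain_heights: dict[str, float],
    percentile: float = 1.0,
) -> tuple[dict[str, StreamlineSet], float]:
    """Remove short spurious AF streamlines by the cohort percentile rule.

    Each subject's median AF streamline length is normalized by that
    subject's brain height; the threshold is the first percentile (linear
    interpolation between order statistics) of this cohort distribution.
    Every streamline whose own normalized length falls below the threshold
    is removed. Returns the filtered sets and the threshold used.
    """
    for sid, h in brain_heights.items():
        if h <= 0:
            raise ValueError(f"non-positive brain height for subject {sid}")
    norm_medians = [
        float(np.median(s.lengths_mm)) / brain_heights[sid]
        for sid, s in af_sets.items()
        if len(s) > 0
    ]
    if len(norm_medians) < 2:
        # cannot form a distribution; pass through unchanged
        return {k: v for k, v in af_sets.items()}, 0.0
    threshold = float(np.percentile(norm_medians, percentile))
    out = {}
    for sid, s in af_sets.items():
        if len(s) == 0:
            out[sid] = s
            continue
        keep = np.flatnonzero(s.lengths_mm / brain_heights[sid] >= threshold)
        out[sid] = s.subset(keep)
    return out, threshold
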