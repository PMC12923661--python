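"""Simulation studies of the pipeline's operating characteristics.

These are the package's own validation experiments, run on scaled-down
synthetic cohorts (smaller head, two tracts, a sparser seed lattice) so
that replicated end-to-end runs stay desk-scale; cohort size stays at 30
paired subjects. Covered: statistical power to detect the injected bundle
compression, spatial recovery of the localized MD elevation, type-I-error
calibration of the along-tract testing battery under the null, SNR-drop
measurement, and two pure-geometry checks (cylinder-diameter formula and
curved-bundle FACT propagation).
"""

from __future__ import annotations

import numpy as np

from .core import Grid, default_scheme
from .dwi import wm_snr
from .gating import apply_gates, classify_drtt
from .phantom import (
    BundleSpec,
    PhantomConfig,
    SurgicalEffect,
    make_bundle_field,
    make_cohort,
    simulate_dwi,
)
from .pipeline import delta_profiles, drtt_gate, run_cohort
from .stats import paired_lmm, percent_change, segment_ztest
from .tracking import TrackingParams, seed_grid, track
from .tractometry import diameter, tract_volume

__all__ = [
    "sim_config",
    "sim_tracking_params",
    "volume_power",
    "md_window_recovery",
    "null_calibration",
    "snr_drop_measurement",
    "cylinder_diameter_check",
    "quarter_circle_check",
]


def sim_config(null: bool = False, sides: tuple[str, ...] = ("left",)) -> PhantomConfig:
    """Scaled-down cohort conditions for replicated simulations.

    Two tracts (d-DRTT and AF) on an 18 x 18 x 24 grid, left hemisphere
    only by default (the replicated analyses test left-side panels); the
    injected effects keep the study defaults: d-DRTT compression to 70%
    radius, MD elevation in the left dentate-end window, 9.4% SNR drop,
    mild AF compression. ``null=True`` removes every injected effect.
    """
    effects = () if null else (
        SurgicalEffect(
            volume_scale=0.7,
            md_delta=0.4e-3,
            md_window=(0.0, 0.2),
            snr_scale=0.906,
            applies_to=("d_DRTT/left",),
        ),
        SurgicalEffect(volume_scale=0.7, applies_to=("d_DRTT/right",)),
        SurgicalEffect(volume_scale=0.95, applies_to=("AF",)),
    )
    return PhantomConfig(
        grid_shape=(18, 18, 24), tracts=("d_DRTT", "AF"), sides=sides, effects=effects
    )


def sim_tracking_params() -> TrackingParams:
    """Replicate-study tracking: study rules, voxel-spaced seed lattice."""
    return TrackingParams(seed_spacing_mm=2.55, max_steps=200)


def _paired_volumes(pair, params: TrackingParams) -> tuple[float, float] | None:
    """Left d-DRTT normalized volume at both timepoints of one subject."""
    out = []
    for ds in (pair.pre, pair.intra):
        wm = ds.masks["white_matter"]
        seeds = seed_grid(wm, ds.grid, params.seed_spacing_mm)
        sls = track(ds.peaks, params, wm, seeds)
        gated = apply_gates(sls, drtt_gate(ds.masks, "left"), ds.grid)
        motor = {s: ds.masks[f"motor_cortex_{s}"] for s in ("left", "right")}
        d_set = classify_drtt(gated, "left", motor, ds.grid)["d_DRTT"]
        if len(d_set) == 0:
            return None
        _, vnorm = tract_volume(d_set, ds.grid, ds.masks["supratentorial_wm"])
        out.append(vnorm)
    return out[0], out[1]


def volume_power(
    n_replicates: int = 100, seed: int = 0, n_subjects: int = 30
) -> dict:
    """Fraction of cohort replicates detecting the injected compression.

    Each replicate generates a fresh 30-subject cohort with left d-DRTT
    compression (radius scale 0.7), runs tracking + gating + volume, and
    tests the paired timepoint effect with the random-intercept mixed
    model. Detection = p < 0.05 with a negative volume estimate.
    """
    from dataclasses import replace as _replace

    cfg = _replace(sim_config(), simulate_signal=False)  # volumes need no DWI
    params = sim_tracking_params()
    rng = np.random.default_rng(seed)
    hits, changes = 0, []
    for _ in range(n_replicates):
        pairs = make_cohort(n_subjects, int(rng.integers(2**31 - 1)), cfg)
        pre, intra, subj = [], [], []
        for p in pairs:
            res = _paired_volumes(p, params)
            if res is None:
                continue
            pre.append(res[0])
            intra.append(res[1])
            subj.append(p.subject_id)
        vals = np.column_stack([pre, intra]).ravel()
        tp = np.tile([0.0, 1.0], len(subj))
        r = paired_lmm(vals, tp, np.repeat(subj, 2))
        if r.p_raw < 0.05 and r.statistic < 0:
            hits += 1
        changes.append(percent_change(np.mean(pre), np.mean(intra)))
    return {
        "power": hits / n_replicates,
        "mean_volume_change_pct": float(np.mean(changes)),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def md_window_recovery(seed: int = 0, n_subjects: int = 30, n_segments: int = 55) -> dict:
    """Variance localization of the injected dentate-end MD elevation.

    Runs the full pipeline on one cohort and compares the across-subject
    variance of the per-segment MD change inside the injected arc window
    (plus one segment of slack) against the remaining segments of the left
    d-DRTT; the AF profile variance ratio is reported as the control.
    """
    cfg = sim_config()
    pairs = make_cohort(n_subjects, seed, cfg)
    tables = run_cohort(pairs, sim_tracking_params(), n_segments)
    a, b = cfg.effects[0].md_window
    lo = max(int(np.floor(a * n_segments)) - 1, 0)  # window +/- 1 segment, 0-based
    hi = min(int(np.ceil(b * n_segments)) + 1, n_segments)

    def ratio(tract: str, side: str) -> float:
        delta = delta_profiles(tables["profiles"], tract, side, "MD").to_numpy()
        var = np.nanvar(delta, axis=0, ddof=1)
        inside = np.nanmean(var[lo:hi])
        outside = np.nanmean(var[np.r_[0:lo, hi:n_segments]]) if hi < n_segments else np.nan
        return float(inside / outside)

    return {
        "variance_ratio_d_drtt_left": ratio("d_DRTT", "left"),
        "variance_ratio_af_left": ratio("AF", "left"),
        "window_segments": (lo + 1, hi),
        "n_subjects": n_subjects,
    }


def null_calibration(
    n_replicates: int = 200, seed: int = 0, n_subjects: int = 30, n_segments: int = 55
) -> dict:
    """Type-I error of the along-tract battery with no injected effects.

    A panel is one metric x tract x side family of segment z-tests with BH
    correction; the reported rate is the fraction of panels showing any
    BH-significant segment at 0.05, with its Monte-Carlo standard error.
    """
    cfg = sim_config(null=True)
    params = sim_tracking_params()
    rng = np.random.default_rng(seed)
    n_sig, n_panels = 0, 0
    for _ in range(n_replicates):
        pairs = make_cohort(n_subjects, int(rng.integers(2**31 - 1)), cfg)
        tables = run_cohort(pairs, params, n_segments)
        for tract in cfg.tracts:
            for side in cfg.sides:
                for metric in ("FA", "MD"):
                    delta = delta_profiles(tables["profiles"], tract, side, metric)
                    if delta.empty:
                        continue
                    res = segment_ztest(delta.to_numpy())
                    n_panels += 1
                    if (res.p_fdr[res.tested] < 0.05).any():
                        n_sig += 1
    rate = n_sig / n_panels
    return {
        "panel_rate": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / n_panels)),
        "n_panels": n_panels,
        "n_replicates": n_replicates,
    }


def snr_drop_measurement(
    seed: int = 0, snr_pre: float = 24.0, snr_scale: float = 0.906, n_wm_voxels: int = 512
) -> dict:
    """Measured WM SNR at two noise levels and the resulting percent change.

    Simulates the full two-shell acquisition over an isotropic white-matter
    slab and applies the b0-series SNR estimator at the pre level and after
    scaling the noise by 1/snr_scale.
    """
    side = int(np.ceil(n_wm_voxels ** (1 / 3))) + 2
    grid_shape = (side, side, side)
    scheme = default_scheme(grid_shape)
    wm = np.zeros(grid_shape, dtype=bool)
    wm[1:-1, 1:-1, 1:-1] = True
    tensors = np.zeros(grid_shape + (3, 3))
    tensors[wm] = 0.7e-3 * np.eye(3)
    out = {}
    for name, snr in (("pre", snr_pre), ("intra", snr_pre * snr_scale)):
        dwi = simulate_dwi(tensors, scheme, snr, seed + (0 if name == "pre" else 1), mask=wm)
        out[name], _ = wm_snr(dwi[..., scheme.b0_mask], wm)
    out["percent_change"] = percent_change(out["pre"], out["intra"])
    out["n_wm_voxels"] = int(wm.sum())
    return out


def cylinder_diameter_check(radius_mm: float = 4.0, length_mm: float = 40.0,
                            voxel_mm: float = 2.55) -> dict:
    """Diameter formula on an analytically voxelized cylinder."""
    margin = 3 * voxel_mm
    nz = int(np.ceil((length_mm + 2 * margin) / voxel_mm))
    nxy = int(np.ceil((2 * radius_mm + 2 * margin) / voxel_mm))
    grid = Grid((nxy, nxy, nz), voxel_mm)
    centers = grid.voxel_centers().reshape(grid.shape + (3,))
    # axis through a voxel center; a corner-aligned axis is a degenerate
    # rasterization that no tracked bundle exhibits
    axis_xy = (np.array([nxy // 2, nxy // 2]) + 0.5) * voxel_mm
    z0 = margin
    in_cyl = (
        (np.linalg.norm(centers[..., :2] - axis_xy, axis=-1) <= radius_mm)
        & (centers[..., 2] >= z0)
        & (centers[..., 2] <= z0 + length_mm)
    )
    volume = float(in_cyl.sum()) * grid.voxel_volume_mm3
    d = diameter(volume, length_mm)
    return {
        "diameter_mm": d,
        "expected_mm": 2 * radius_mm,
        "rel_error_pct": 100.0 * abs(d - 2 * radius_mm) / (2 * radius_mm),
    }


def quarter_circle_check(arc_radius_mm: float = 40.0, tube_radius_mm: float = 3.0,
                         voxel_mm: float = 1.5) -> dict:
    """FACT traversal of a quarter-circle bundle vs the analytic arc length.

    The tube's peak field is embedded in a wider white-matter mask so the
    track ends by the amplitude rule exactly at the tube (per-step turn at
    1-mm steps is ~1.4 degrees, far below the 60-degree limit).
    """
    margin = 6 * voxel_mm
    extent = arc_radius_mm + tube_radius_mm + 2 * margin
    shape = (int(np.ceil(extent / voxel_mm)), int(np.ceil((2 * tube_radius_mm + 2 * margin) / voxel_mm)),
             int(np.ceil(extent / voxel_mm)))
    scheme = default_scheme(shape, voxel_mm)
    grid = scheme.grid
    theta = np.linspace(0, np.pi / 2, 12)
    y0 = grid.extent_mm[1] / 2
    pts = np.stack(
        [margin + arc_radius_mm * np.sin(theta), np.full_like(theta, y0),
         margin + arc_radius_mm * np.cos(theta)], axis=1
    )
    spec = BundleSpec("AF", "left", pts, tube_radius_mm, False, ("wernicke", "broca"))
    bf = make_bundle_field(spec, scheme)
    # trim the rasterized tube's spherical end caps so the bundle spans the
    # angular quarter exactly
    centers = grid.voxel_centers().reshape(grid.shape + (3,))
    rel = centers - np.array([margin, 0.0, margin])
    ang = np.arctan2(rel[..., 0], rel[..., 2])
    band = (ang >= 0.0) & (ang <= np.pi / 2)
    bf.peaks.amps[~band] = 0.0
    wm = np.ones(grid.shape, dtype=bool)  # termination by amplitude, not mask
    params = TrackingParams(max_steps=300)
    mid = pts[len(pts) // 2]
    sls = track(bf.peaks, params, wm, mid[None, :])
    length = float(sls.lengths_mm[0])
    expected = np.pi * arc_radius_mm / 2
    return {
        "tracked_length_mm": length,
        "expected_mm": float(expected),
        "rel_error_pct": 100.0 * abs(length - expected) / expected,
    }
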