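"""Paired pre/intraoperative synthetic datasets with known ground truth.

Each synthetic patient is a small "head": tube-shaped fiber bundles —
decussating and non-decussating dentato-rubro-thalamic tracts (d-DRTT,
nd-DRTT) that run from a cerebellar dentate nucleus through the (contra- or
ipsilateral) thalamus to the motor cortex, and an arcuate fasciculus (AF)
arcing between temporal (Wernicke) and frontal (Broca) regions — embedded
in a white-matter mask with a gray-matter shell, ventricles and a posterior
fossa tumor. Bundle voxels carry a single fiber peak tangent to the bundle
spine and an axially symmetric diffusion tensor; the DWI signal follows the
mono-exponential tensor model with Rician noise at a controllable SNR.

The intraoperative dataset of a pair is the preoperative geometry
regenerated with injected surgical effects: bundle compression (radius
scale), a localized mean-diffusivity elevation near the dentate end, a
global SNR drop, and an emptied tumor mask (complete resection). The binary
speech-disturbance label is tied to the injected left-sided MD effect, with
a configurable random component. Every applied effect is recorded in the
pair's truth dictionary, so downstream recovery can be checked without
re-deriving anything from images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .core import AcquisitionScheme, Grid, PeakVolume, default_scheme

__all__ = [
    "GeometryError",
    "BundleSpec",
    "SurgicalEffect",
    "MaskSet",
    "BundleField",
    "SubjectDataset",
    "SubjectPair",
    "PhantomConfig",
    "make_bundle_field",
    "simulate_dwi",
    "make_subject_pair",
    "make_cohort",
    "default_bundle_specs",
]

MASK_NAMES = (
    "white_matter",
    "gray_matter",
    "csf",
    "ventricles",
    "tumor",
    "dentate_left",
    "dentate_right",
    "thalamus_left",
    "thalamus_right",
    "motor_cortex_left",
    "motor_cortex_right",
    "corpus_callosum",
    "wernicke_left",
    "wernicke_right",
    "broca_left",
    "broca_right",
    "supratentorial_wm",
)


class GeometryError(ValueError):
    """A bundle spine does not fit inside the grid interior."""


@dataclass(frozen=True)
class BundleSpec:
    """Tube bundle defined by a spine through >= 4 control points (mm)."""

    name: str  # d_DRTT | nd_DRTT | AF
    side: str  # left | right (hemisphere of the dentate / Wernicke end)
    control_points: np.ndarray  # (n, 3) mm
    radius_mm: float
    decussates: bool
    endpoint_rois: tuple[str, str]

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        object.__setattr__(self, "control_points", pts)
        if pts.shape[0] < 4 or pts.shape[1] != 3:
            raise ValueError("need >= 4 control points of dim 3")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.decussates != (self.name == "d_DRTT"):
            raise ValueError("only (and exactly) the d_DRTT decussates")

    @property
    def key(self) -> str:
        return f"{self.name}/{self.side}"


@dataclass(frozen=True)
class SurgicalEffect:
    """Injected intraoperative change, recorded verbatim in the truth record.

    volume_scale multiplies the bundle radius (<= 1 means compression);
    md_delta (mm^2/s) is added to the tensor eigenvalues inside the
    md_window, an arc-length-fraction interval measured from the dentate
    (or Wernicke) end; snr_scale multiplies the subject's SNR.
    """

    volume_scale: float = 1.0
    md_delta: float = 0.0
    md_window: tuple[float, float] = (0.0, 0.2)
    snr_scale: float = 1.0
    applies_to: tuple[str, ...] = ()  # bundle keys "name/side" or names

    def __post_init__(self) -> None:
        if not 0 < self.volume_scale <= 1.5:
            raise ValueError("volume_scale must lie in (0, 1.5]")
        a, b = self.md_window
        if not 0 <= a < b <= 1:
            raise ValueError("md_window must satisfy 0 <= a < b <= 1")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be positive")

    def matches(self, spec: BundleSpec) -> bool:
        return spec.key in self.applies_to or spec.name in self.applies_to


@dataclass
class MaskSet:
    """Named binary masks on one grid; tissue classes are pairwise disjoint."""

    masks: dict[str, np.ndarray]
    grid: Grid

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def brain(self) -> np.ndarray:
        return (
            self.masks["white_matter"]
            | self.masks["gray_matter"]
            | self.masks["csf"]
            | self.masks["tumor"]
        )


@dataclass
class BundleField:
    """Rasterized bundle: peaks, tensors, mask and per-voxel arc fraction."""

    peaks: PeakVolume
    tensors: np.ndarray  # (X, Y, Z, 3, 3); zero outside the bundle
    mask: np.ndarray
    arc_frac: np.ndarray  # (X, Y, Z); NaN outside the bundle


@dataclass
class SubjectDataset:
    """One timepoint of one synthetic patient."""

    scheme: AcquisitionScheme
    masks: MaskSet
    peaks: PeakVolume
    tensors: np.ndarray
    dwi: np.ndarray
    snr: float
    bundle_masks: dict[str, np.ndarray]
    bundle_specs: dict[str, BundleSpec]

    @property
    def grid(self) -> Grid:
        return self.scheme.grid


@dataclass
class SubjectPair:
    subject_id: str
    age_years: float
    sex: str  # 'F' | 'M'
    pre: SubjectDataset
    intra: SubjectDataset
    truth: dict
    speech_increase: bool


# ---------------------------------------------------------------------------
# geometry

_LAM_PAR = 1.7e-3  # bundle axial diffusivity, mm^2/s
_LAM_PERP = 0.3e-3  # bundle radial diffusivity
_MD_WM = 0.7e-3  # isotropic background white matter
_MD_GM = 0.9e-3
_MD_CSF = 3.0e-3
_MD_TUMOR = 1.2e-3
_S0 = 100.0
_PEAK_AMP = 0.5


def _spine(spec: BundleSpec, sample_mm: float = 0.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense spine samples, unit tangents, and arc-length fractions."""
    pts = spec.control_points
    tck, _ = splprep(pts.T, s=0, k=min(3, pts.shape[0] - 1))
    u = np.linspace(0, 1, 256)
    xyz = np.stack(splev(u, tck), axis=1)
    arc = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))])
    n = max(int(arc[-1] / sample_mm), 8)
    t = np.linspace(0, arc[-1], n)
    uu = np.interp(t, arc, u)
    xyz = np.stack(splev(uu, tck), axis=1)
    tan = np.stack(splev(uu, tck, der=1), axis=1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return xyz, tan, t / arc[-1]


def make_bundle_field(
    spec: BundleSpec,
    scheme: AcquisitionScheme,
    md_delta: float = 0.0,
    md_window: tuple[float, float] = (0.0, 0.2),
    peak_amplitude: float = _PEAK_AMP,
    halo_mm: float | None = None,
) -> BundleField:
    """Rasterize one bundle onto the scheme's grid.

    Voxels whose center lies within ``radius_mm`` of the spine carry a
    single peak tangent to the spine and an axially symmetric tensor
    (lambda_par 1.7e-3, lambda_perp 0.3e-3 mm^2/s); ``md_delta`` is added
    isotropically inside the arc-fraction window. A one-voxel orientation
    halo (partial-volume rim) extends the peak field beyond the tube so
    voxel-quantized propagation does not fall off the bundle edge; the
    bundle mask and tensors stay confined to the tube. The spine must stay
    at least two voxels away from every grid face.
    """
    grid = scheme.grid
    if halo_mm is None:
        # rim scales with caliber (a thinner bundle has a thinner partial-
        # volume rim), capped at one voxel
        halo_mm = min(grid.voxel_size_mm, 0.7 * spec.radius_mm)
    xyz, tan, frac = _spine(spec)
    margin = 2 * grid.voxel_size_mm
    if np.any(xyz < margin) or np.any(xyz > grid.extent_mm - margin):
        raise GeometryError(f"spine of {spec.key} leaves the grid interior (2-voxel margin)")

    reach = spec.radius_mm + halo_mm
    lo = grid.world_to_voxel(xyz.min(axis=0) - reach - grid.voxel_size_mm)
    hi = grid.world_to_voxel(xyz.max(axis=0) + reach + grid.voxel_size_mm) + 1
    lo = np.clip(lo, 0, np.asarray(grid.shape))
    hi = np.clip(hi, 0, np.asarray(grid.shape))
    sub_idx = (
        np.stack(
            np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"), axis=-1
        )
        .reshape(-1, 3)
    )
    centers = (sub_idx + 0.5) * grid.voxel_size_mm
    dist, nearest = cKDTree(xyz).query(centers)
    in_halo = dist <= reach
    inside = dist <= spec.radius_mm
    idx = sub_idx[inside]
    near = nearest[inside]

    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(idx.T)] = True
    halo_mask = np.zeros(grid.shape, dtype=bool)
    halo_mask[tuple(sub_idx[in_halo].T)] = True
    arc_frac = np.full(grid.shape, np.nan)
    arc_frac[tuple(idx.T)] = frac[near]

    tensors = np.zeros(grid.shape + (3, 3))
    t = tan[near]
    d = _LAM_PERP * np.eye(3)[None] + (_LAM_PAR - _LAM_PERP) * np.einsum("ni,nj->nij", t, t)
    if md_delta:
        a, b = md_window
        in_win = (frac[near] >= a) & (frac[near] <= b)
        d = d + md_delta * np.eye(3)[None] * in_win[:, None, None]
    tensors[tuple(idx.T)] = d

    peaks = PeakVolume.empty(grid)
    peaks.add_peaks(halo_mask, tan[nearest[in_halo]], peak_amplitude)
    return BundleField(peaks=peaks, tensors=tensors, mask=mask, arc_frac=arc_frac)


_INTERIOR_MARGIN = 6.0  # mm kept clear of every grid face by the default geometry


def _frac_to_mm(frac, extent_mm: np.ndarray) -> np.ndarray:
    """Map fractional coordinates into the grid interior (margin-aware)."""
    return _INTERIOR_MARGIN + np.asarray(frac, dtype=float) * (extent_mm - 2 * _INTERIOR_MARGIN)


def _sphere(grid: Grid, center_frac, radius_mm: float) -> np.ndarray:
    centers = grid.voxel_centers()
    c = _frac_to_mm(center_frac, grid.extent_mm)
    m = np.linalg.norm(centers - c, axis=1) <= radius_mm
    return m.reshape(grid.shape)


def _box(grid: Grid, lo_frac, hi_frac) -> np.ndarray:
    centers = grid.voxel_centers().reshape(grid.shape + (3,))
    lo = _frac_to_mm(lo_frac, grid.extent_mm)
    hi = _frac_to_mm(hi_frac, grid.extent_mm)
    return np.all((centers >= lo) & (centers <= hi), axis=-1)


# fractional control points of the default bundle geometry; x is left-right
# (left = x < 0.5), y anterior-posterior, z feet-head
_CTRL = {
    "d_DRTT": [(0.35, 0.44, 0.12), (0.44, 0.44, 0.20), (0.58, 0.44, 0.32),
               (0.62, 0.44, 0.50), (0.62, 0.44, 0.68), (0.60, 0.44, 0.85)],
    "nd_DRTT": [(0.31, 0.44, 0.12), (0.33, 0.44, 0.30), (0.36, 0.44, 0.50),
                (0.38, 0.44, 0.68), (0.38, 0.44, 0.85)],
    "AF": [(0.18, 0.74, 0.55), (0.18, 0.70, 0.72), (0.18, 0.50, 0.80),
           (0.18, 0.30, 0.72), (0.18, 0.28, 0.58)],
}
_ENDPOINTS = {
    "d_DRTT": ("dentate", "motor_cortex"),
    "nd_DRTT": ("dentate", "motor_cortex"),
    "AF": ("wernicke", "broca"),
}


def default_bundle_specs(
    grid: Grid,
    tracts: tuple[str, ...] = ("d_DRTT", "nd_DRTT", "AF"),
    sides: tuple[str, ...] = ("left", "right"),
    radius_mm: float = 3.5,
) -> list[BundleSpec]:
    """Bundle geometry of the default synthetic head.

    Left-sided bundles run at y = 0.44 of the grid depth, right-sided ones
    mirrored in x at y = 0.56, which keeps the two decussating DRTTs from
    overlapping at the midline.
    """
    specs = []
    for name in tracts:
        for side in sides:
            pts = np.array(_CTRL[name], dtype=float)
            if side == "right":
                pts[:, 0] = 1.0 - pts[:, 0]
                pts[:, 1] = 1.0 - 0.44 + (pts[:, 1] - 0.44)  # y = 0.56 lane
            e0, e1 = _ENDPOINTS[name]
            if name == "d_DRTT":
                contra = "right" if side == "left" else "left"
                rois = (f"{e0}_{side}", f"{e1}_{contra}")
            else:
                rois = (f"{e0}_{side}", f"{e1}_{side}")
            specs.append(
                BundleSpec(
                    name=name,
                    side=side,
                    control_points=_frac_to_mm(pts, grid.extent_mm),
                    radius_mm=radius_mm,
                    decussates=(name == "d_DRTT"),
                    endpoint_rois=rois,
                )
            )
    return specs


def _make_masks(
    grid: Grid,
    bundle_fields: dict[str, BundleField],
    ventricle_scale: float = 1.0,
    tumor_present: bool = True,
) -> MaskSet:
    """Assemble the tissue and ROI masks around rasterized bundles.

    Tissue classes are made pairwise disjoint by priority
    WM > GM > CSF/ventricles > tumor.
    """
    wm = np.zeros(grid.shape, dtype=bool)
    for bf in bundle_fields.values():
        wm |= bf.mask
    # two dilation passes so the white matter encloses the bundles' partial-
    # volume orientation halo; termination then happens at a true GM-WM rim
    wm = binary_dilation(wm, iterations=2)
    gm = binary_dilation(wm, iterations=1) & ~wm

    vhalf = np.array([0.05, 0.045, 0.10]) * ventricle_scale
    vent = _box(grid, np.array([0.5, 0.5, 0.60]) - vhalf, np.array([0.5, 0.5, 0.60]) + vhalf)
    vent &= ~(wm | gm)
    tumor = np.zeros(grid.shape, dtype=bool)
    if tumor_present:
        tumor = _sphere(grid, (0.5, 0.80, 0.12), 6.0) & ~(wm | gm | vent)

    rois = {
        "dentate_left": _sphere(grid, (0.33, 0.44, 0.11), 7.0),
        "dentate_right": _sphere(grid, (0.67, 0.56, 0.11), 7.0),
        "thalamus_left": _sphere(grid, (0.37, 0.50, 0.50), 8.0),
        "thalamus_right": _sphere(grid, (0.63, 0.50, 0.50), 8.0),
        "motor_cortex_left": _sphere(grid, (0.39, 0.50, 0.86), 9.0),
        "motor_cortex_right": _sphere(grid, (0.61, 0.50, 0.86), 9.0),
        "corpus_callosum": _box(grid, (0.45, 0.40, 0.91), (0.55, 0.60, 0.97)),
        "wernicke_left": _sphere(grid, (0.18, 0.76, 0.54), 7.0),
        "wernicke_right": _sphere(grid, (0.82, 0.76, 0.54), 7.0),
        "broca_left": _sphere(grid, (0.18, 0.26, 0.57), 7.0),
        "broca_right": _sphere(grid, (0.82, 0.26, 0.57), 7.0),
    }
    zc = np.zeros(grid.shape, dtype=bool)
    zc[:, :, int(0.22 * grid.shape[2]) :] = True  # tentorium plane
    masks = {
        "white_matter": wm,
        "gray_matter": gm,
        "csf": vent.copy(),
        "ventricles": vent,
        "tumor": tumor,
        "supratentorial_wm": wm & zc,
        **rois,
    }
    return MaskSet(masks=masks, grid=grid)


# ---------------------------------------------------------------------------
# signal


def simulate_dwi(
    tensors: np.ndarray,
    scheme: AcquisitionScheme,
    snr: float,
    seed: int,
    mask: np.ndarray | None = None,
    s0: float = _S0,
) -> np.ndarray:
    """Mono-exponential tensor signal S = S0 exp(-b g^T D g) with Rician noise.

    Noise: magnitude of (signal + N(0, sigma), N(0, sigma)) with
    sigma = S0 / snr. Reproducible under a fixed seed. Tensors inside the
    mask must be positive semidefinite.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    grid_shape = tensors.shape[:3]
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    d = tensors[mask]  # (n, 3, 3)
    ev = np.linalg.eigvalsh(d)
    if np.any(ev < -1e-12):
        raise ValueError("non-positive-definite tensor inside the simulation mask")
    b, g = scheme.bvals, scheme.bvecs
    quad = np.einsum("vi,nij,vj->nv", g, d, g)  # (n, V)
    signal = s0 * np.exp(-b[None, :] * quad)
    rng = np.random.default_rng(seed)
    if np.isfinite(snr):
        sigma = s0 / snr
        n1 = rng.normal(0, sigma, signal.shape)
        n2 = rng.normal(0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    dwi = np.zeros(grid_shape + (scheme.n_volumes,))
    dwi[mask] = signal
    return dwi


# ---------------------------------------------------------------------------
# subjects and cohorts


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the paired intraoperative study design: a 2.55-mm
    isotropic two-shell acquisition, preoperative white-matter SNR around
    24 (between-subject SD ~4.6), an intraoperative SNR factor of 0.906
    (a ~9.4% drop), d-DRTT compression to 70% radius, a localized MD
    elevation near the left dentate end whose magnitude drives the
    speech-disturbance label, and a mildly compressed AF.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 32)
    voxel_size_mm: float = 2.55
    tracts: tuple[str, ...] = ("d_DRTT", "nd_DRTT", "AF")
    sides: tuple[str, ...] = ("left", "right")
    bundle_radius_mm: float = 3.5
    effects: tuple[SurgicalEffect, ...] = (
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
    snr_pre_mean: float = 24.36
    snr_pre_sd: float = 4.60
    snr_floor: float = 10.0
    jitter_mm: float = 1.2
    radius_jitter: float = 0.1  # uniform +/- fraction
    severity_range: tuple[float, float] = (0.25, 1.75)  # scales md_delta per subject
    speech_md_threshold: float = 0.3e-3
    speech_random_prob: float = 0.05
    age_range_years: tuple[float, float] = (1.75, 17.0)
    ventricle_scale_range: tuple[float, float] = (0.8, 1.25)
    ventricle_coupling: float = 0.0  # >0 couples larger ventricles to stronger compression
    s0: float = _S0
    simulate_signal: bool = True  # False skips DWI synthesis (geometry-only studies)

    def scheme(self) -> AcquisitionScheme:
        return default_scheme(self.grid_shape, self.voxel_size_mm)


def _build_dataset(
    config: PhantomConfig,
    specs: list[BundleSpec],
    per_bundle: dict[str, dict],
    ventricle_scale: float,
    tumor_present: bool,
    snr: float,
    noise_seed: int,
) -> SubjectDataset:
    scheme = config.scheme()
    grid = scheme.grid
    fields: dict[str, BundleField] = {}
    for spec in specs:
        eff = per_bundle.get(spec.key, {})
        s = replace(spec, radius_mm=spec.radius_mm * eff.get("volume_scale", 1.0))
        fields[spec.key] = make_bundle_field(
            s,
            scheme,
            md_delta=eff.get("md_delta", 0.0),
            md_window=eff.get("md_window", (0.0, 0.2)),
        )
    masks = _make_masks(grid, fields, ventricle_scale, tumor_present)

    tensors = np.zeros(grid.shape + (3, 3))
    eye = np.eye(3)
    tensors[masks["white_matter"]] = _MD_WM * eye
    tensors[masks["gray_matter"]] = _MD_GM * eye
    tensors[masks["csf"]] = _MD_CSF * eye
    tensors[masks["tumor"]] = _MD_TUMOR * eye
    peaks = PeakVolume.empty(grid)
    for key, bf in fields.items():
        tensors[bf.mask] = bf.tensors[bf.mask]  # later bundles win in overlaps
        hmask = bf.peaks.amps[..., 0] > 0  # tube + orientation halo
        idx = np.argwhere(hmask)
        peaks.add_peaks(hmask, bf.peaks.dirs[idx[:, 0], idx[:, 1], idx[:, 2], 0], _PEAK_AMP)

    if config.simulate_signal:
        dwi = simulate_dwi(tensors, scheme, snr, noise_seed, mask=masks.brain, s0=config.s0)
    else:
        dwi = np.zeros(grid.shape + (scheme.n_volumes,))
    return SubjectDataset(
        scheme=scheme,
        masks=masks,
        peaks=peaks,
        tensors=tensors,
        dwi=dwi,
        snr=snr,
        bundle_masks={k: f.mask for k, f in fields.items()},
        bundle_specs={s.key: s for s in specs},
    )


def make_subject_pair(config: PhantomConfig, seed: int, subject_id: str = "sub-000") -> SubjectPair:
    """One synthetic patient: a pre/intra dataset pair plus ground truth.

    The pre and intra datasets share subject geometry (jittered control
    points, per-subject radius) and acquisition scheme; the intra dataset
    applies the configured surgical effects and a fresh noise realization.
    """
    if not config.effects and not config.tracts:
        raise ValueError("config must name at least one bundle")
    rng = np.random.default_rng(seed)
    grid = config.scheme().grid
    base = default_bundle_specs(grid, config.tracts, config.sides, config.bundle_radius_mm)
    r_jit = 1.0 + rng.uniform(-config.radius_jitter, config.radius_jitter)
    # keep jittered spines in the interior, with headroom for spline overshoot
    margin = 2 * config.voxel_size_mm + 4.0
    hard = 2 * config.voxel_size_mm  # the rasterizer's own safety bound
    jitters = [rng.normal(0, config.jitter_mm, s.control_points.shape) for s in base]
    # a zigzag draw can make the interpolating spline overshoot the clipped
    # control polygon; deterministically damp the jitter until every spine
    # stays inside (scale 0 reproduces the always-valid base geometry)
    for attempt in range(8):
        scale = 0.5**attempt
        specs = [
            replace(
                s,
                control_points=np.clip(
                    s.control_points + scale * j, margin, grid.extent_mm - margin
                ),
                radius_mm=s.radius_mm * r_jit,
            )
            for s, j in zip(base, jitters)
        ]
        ok = True
        for s in specs:
            xyz, _, _ = _spine(s)
            if np.any(xyz < hard) or np.any(xyz > grid.extent_mm - hard):
                ok = False
                break
        if ok:
            break
    severity = rng.uniform(*config.severity_range)
    ventricle_scale = rng.uniform(*config.ventricle_scale_range)
    snr_pre = max(rng.normal(config.snr_pre_mean, config.snr_pre_sd), config.snr_floor)
    age = rng.uniform(*config.age_range_years)
    sex = "F" if rng.random() < 0.5 else "M"

    per_bundle: dict[str, dict] = {}
    snr_scale = 1.0
    for eff in config.effects:
        snr_scale *= eff.snr_scale
        for spec in specs:
            if eff.matches(spec):
                vs = eff.volume_scale
                if config.ventricle_coupling:
                    vs = float(
                        np.clip(vs - config.ventricle_coupling * (ventricle_scale - 1.0), 0.2, 1.5)
                    )
                per_bundle[spec.key] = {
                    "volume_scale": vs,
                    "md_delta": eff.md_delta * severity,
                    "md_window": eff.md_window,
                }

    pre = _build_dataset(
        config, specs, {}, ventricle_scale, True, snr_pre, int(rng.integers(2**31))
    )
    intra = _build_dataset(
        config,
        specs,
        per_bundle,
        ventricle_scale,
        False,
        snr_pre * snr_scale,
        int(rng.integers(2**31)),
    )

    md_rule = any(
        k.endswith("/left") and e["md_delta"] > config.speech_md_threshold
        for k, e in per_bundle.items()
    )
    random_draw = bool(rng.random() < config.speech_random_prob)
    speech = md_rule or random_draw
    truth = {
        "subject_id": subject_id,
        "effects": {k: dict(v) for k, v in per_bundle.items()},
        "severity": float(severity),
        "snr_pre": float(snr_pre),
        "snr_scale": float(snr_scale),
        "ventricle_scale": float(ventricle_scale),
        "speech_rule": {
            "md_threshold": config.speech_md_threshold,
            "md_rule_fired": md_rule,
            "random_draw": random_draw,
        },
    }
    return SubjectPair(
        subject_id=subject_id,
        age_years=float(age),
        sex=sex,
        pre=pre,
        intra=intra,
        truth=truth,
        speech_increase=speech,
    )


def make_cohort(n: int, seed: int, config: PhantomConfig | None = None) -> list[SubjectPair]:
    """A cohort of paired synthetic patients with independent geometry/noise."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        make_subject_pair(config, int(s), subject_id=f"sub-{i:03d}")
        for i, s in enumerate(sub_seeds)
    ]
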