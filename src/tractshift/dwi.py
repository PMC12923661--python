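"""Diffusion-tensor fitting and scalar microstructure maps (FA, MD) plus the
white-matter SNR statistic.

The tensor is estimated by ordinary (unweighted) least squares on the
log-signal — the reproducible baseline when the estimator is otherwise a free
choice. Voxels containing non-positive signal are marked invalid rather than
imputed. Negative eigenvalues are clamped to zero before FA/MD and the clamp
count is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionScheme, Grid

__all__ = ["TensorMap", "design_matrix", "fit_tensor", "fa", "md", "fa_md_maps", "wm_snr"]

# index order of the 6 unique tensor elements in the fitted coefficient vector
_TENSOR_ELEMS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorMap:
    """Per-voxel symmetric diffusion tensors (mm^2/s) with S0 and validity."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3)
    s0: np.ndarray  # (X, Y, Z)
    valid: np.ndarray  # (X, Y, Z) bool
    grid: Grid
    n_clamped: int = field(default=0)

    def eigenvalues(self) -> np.ndarray:
        """Ascending eigenvalues on valid voxels, clamped at zero; NaN elsewhere."""
        evals = np.full(self.tensors.shape[:3] + (3,), np.nan)
        if self.valid.any():
            ev = np.linalg.eigvalsh(self.tensors[self.valid])
            n_neg = int((ev < 0).sum())
            if n_neg:
                ev = np.clip(ev, 0, None)
                self.n_clamped += n_neg
            evals[self.valid] = ev
        return evals


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Log-linear tensor design: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]."""
    b, g = scheme.bvals, scheme.bvecs
    cols = [np.ones_like(b)]
    for k, (i, j) in enumerate(_TENSOR_ELEMS):
        w = 1.0 if i == j else 2.0
        cols.append(-w * b * g[:, i] * g[:, j])
    return np.stack(cols, axis=1)


def fit_tensor(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    b_max: float | None = None,
) -> TensorMap:
    """Ordinary least-squares log-linear tensor fit inside ``mask``.

    Requires at least 7 volumes including one b0. Voxels with any
    non-positive signal are invalid (excluded, never imputed). By default
    all shells enter the fit; ``b_max`` restricts it to volumes with
    b-value <= b_max (e.g. 1000 for a single-shell fit).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != scheme.n_volumes:
        raise ValueError("dwi must be 4D with one volume per scheme entry")
    if b_max is not None:
        keep = scheme.bvals <= b_max
        scheme = AcquisitionScheme(
            scheme.bvals[keep], scheme.bvecs[keep], scheme.voxel_size_mm, scheme.grid_shape
        )
        dwi = dwi[..., keep]
    if scheme.n_volumes < 7 or not scheme.b0_mask.any():
        raise ValueError("need >= 7 volumes including >= 1 b0")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate design matrix: directions do not span the tensor space")
    grid = Grid(dwi.shape[:3], scheme.voxel_size_mm)
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)

    signals = dwi[mask]  # (n, V)
    positive = np.all(signals > 0, axis=1)
    valid = np.zeros(dwi.shape[:3], dtype=bool)
    valid[mask] = positive

    tensors = np.zeros(dwi.shape[:3] + (3, 3))
    s0 = np.zeros(dwi.shape[:3])
    if positive.any():
        beta = np.linalg.pinv(X) @ np.log(signals[positive]).T  # (7, n)
        s0_v = np.exp(beta[0])
        d = np.zeros((beta.shape[1], 3, 3))
        for k, (i, j) in enumerate(_TENSOR_ELEMS):
            d[:, i, j] = beta[1 + k]
            d[:, j, i] = beta[1 + k]
        full = np.zeros(dwi.shape[:3] + (3, 3))
        full_s0 = np.zeros(dwi.shape[:3])
        sub_t = np.zeros((signals.shape[0], 3, 3))
        sub_t[positive] = d
        sub_s = np.zeros(signals.shape[0])
        sub_s[positive] = s0_v
        full[mask] = sub_t
        full_s0[mask] = sub_s
        tensors, s0 = full, full_s0
    return TensorMap(tensors=tensors, s0=s0, valid=valid, grid=grid)


def md(tensor: np.ndarray) -> float:
    """Mean diffusivity: trace / 3, in mm^2/s."""
    t = np.asarray(tensor, dtype=float)
    return float(np.trace(t) / 3.0)


def fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy, sqrt(3/2) * ||lambda - MD|| / ||lambda||.

    Eigenvalues are clamped at zero first; the all-zero tensor has FA 0.
    """
    ev = np.clip(np.linalg.eigvalsh(np.asarray(tensor, dtype=float)), 0, None)
    norm = np.linalg.norm(ev)
    if norm == 0:
        return 0.0
    m = ev.mean()
    return float(np.sqrt(1.5) * np.linalg.norm(ev - m) / norm)


def fa_md_maps(tmap: TensorMap) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD maps over the valid voxels of a TensorMap (NaN elsewhere)."""
    ev = tmap.eigenvalues()
    md_map = ev.mean(axis=-1)
    m = md_map[..., None]
    norm = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa_map = np.sqrt(1.5) * np.sqrt(((ev - m) ** 2).sum(axis=-1)) / norm
    fa_map = np.where(norm == 0, 0.0, fa_map)
    fa_map[~tmap.valid] = np.nan
    md_map[~tmap.valid] = np.nan
    return fa_map, md_map


def wm_snr(b0_volumes: np.ndarray, wm_mask: np.ndarray, ddof: int = 1) -> tuple[float, int]:
    """White-matter SNR of the b0 series.

    Per voxel: temporal mean of the b0 signal divided by its temporal
    standard deviation (sample SD, ``ddof=1``); the statistic is the average
    of that ratio over white-matter voxels. Voxels with zero SD are excluded;
    their count is returned alongside.
    """
    b0 = np.asarray(b0_volumes, dtype=float)
    if b0.ndim != 4 or b0.shape[3] < 2:
        raise ValueError("need a 4D stack of >= 2 b0 volumes")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    sig = b0[wm_mask]  # (n, T)
    mean = sig.mean(axis=1)
    sd = sig.std(axis=1, ddof=ddof)
    ok = sd > 0
    n_zero_sd = int((~ok).sum())
    if not ok.any():
        raise ValueError("all white-matter voxels have zero temporal SD; SNR undefined")
    return float(np.mean(mean[ok] / sd[ok])), n_zero_sd
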