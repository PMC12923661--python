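"""Readers and writers: NIfTI volumes, FSL bval/bvec, TCK/TRK streamlines,
truth records and tidy CSV tables.

All world coordinates are mm in an RAS-like frame with the voxel-center
convention (world = (index + 0.5) * voxel_size); NIfTI affines encode
exactly this mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .core import AcquisitionScheme, Grid
from .tracking import StreamlineSet

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_tck",
    "load_tck",
    "save_trk",
    "save_truth",
    "load_truth",
]


def save_nifti(data: np.ndarray, grid: Grid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms((grid.voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine); dtype as stored."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def grid_from_affine(affine: np.ndarray, shape) -> Grid:
    vs = float(affine[0, 0])
    if not np.allclose(np.diag(affine)[:3], vs) or not np.allclose(affine[:3, 3], vs / 2):
        raise ValueError("affine is not an isotropic voxel-center mapping")
    return Grid(tuple(shape[:3]), vs)


def save_bvals_bvecs(scheme: AcquisitionScheme, base: str | Path) -> None:
    """FSL-style: one row of b-values; three rows of gradient components."""
    base = Path(base)
    np.savetxt(base.with_suffix(".bval"), scheme.bvals[None], fmt="%.1f")
    np.savetxt(base.with_suffix(".bvec"), scheme.bvecs.T, fmt="%.8f")


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise ValueError("bvec file must have exactly 3 rows")
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bval/bvec volume counts disagree")
    return bvals, bvecs.T


def save_tck(streamlines: StreamlineSet, path: str | Path) -> None:
    """Streamlines in mm (scanner) space."""
    tg = Tractogram([np.asarray(s, dtype=np.float32) for s in streamlines], affine_to_rasmm=np.eye(4))
    TckFile(tg).save(str(path))


def load_tck(path: str | Path) -> StreamlineSet:
    tf = nib.streamlines.load(str(path))
    return StreamlineSet([np.asarray(s, dtype=float) for s in tf.streamlines])


def save_trk(streamlines: StreamlineSet, grid: Grid, path: str | Path) -> None:
    tg = Tractogram([np.asarray(s, dtype=np.float32) for s in streamlines], affine_to_rasmm=np.eye(4))
    hdr = {"voxel_to_rasmm": grid.affine.astype(np.float32), "voxel_sizes": (grid.voxel_size_mm,) * 3,
           "dimensions": grid.shape}
    TrkFile(tg, header=hdr).save(str(path))


def save_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
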