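"""File formats and spatial containers shared across the pipeline.

Volumes are NIfTI-1 (.nii / .nii.gz) via nibabel; gradient tables use the
FSL bval/bvec text dialect (bvec: three whitespace-separated rows of x, y, z
components); streamlines are stored as TRK track files, with a plain-text
fallback (one ``x y z`` line per point, blank line between streamlines).

Coordinate conventions
----------------------
Voxel indices are 0-based.  Streamline points live in world millimetres,
obtained through the volume affine.  Eigenvector signs are never fixed on
disk: every consumer must be antipodally symmetric.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "Volume",
    "RoiMask",
    "FormatError",
    "read_dwi",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_streamlines",
    "read_streamlines",
]

B0_THRESHOLD = 50.0  # s/mm^2; below this a measurement counts as baseline


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


@dataclass
class GradientTable:
    """Diffusion sensitization directions and b-values.

    Parameters
    ----------
    bvecs : (N, 3) array
        Unit gradient directions.  Rows paired with ``b == 0`` may be zero.
    bvals : (N,) array
        Non-negative b-values in s/mm^2.  At least one entry must be a
        baseline (b below ``B0_THRESHOLD``), the S0 measurement.
    """

    bvecs: np.ndarray
    bvals: np.ndarray

    def __post_init__(self) -> None:
        self.bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        if self.bvecs.shape != (self.bvals.size, 3):
            raise FormatError(
                f"gradient table mismatch: {self.bvecs.shape[0]} directions "
                f"vs {self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value in gradient table")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = ~self.b0_mask
        # renormalize almost-unit vectors; reject zero vectors with b > 0
        if np.any(norms[dwi] < 1e-12):
            raise FormatError("zero-norm direction paired with nonzero b-value")
        self.bvecs = self.bvecs.copy()
        self.bvecs[dwi] /= norms[dwi, None]
        if not np.any(self.b0_mask):
            raise FormatError("gradient table has no b=0 (S0) entry")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def __len__(self) -> int:
        return self.bvals.size


@dataclass
class Volume:
    """A 3D or 4D image with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise FormatError(f"volume must be 3D or 4D, got {self.data.ndim}D")

    @classmethod
    def from_voxel_size(cls, data: np.ndarray, voxel_size) -> "Volume":
        vs = np.asarray(voxel_size, dtype=float)
        if vs.size != 3 or np.any(vs <= 0):
            raise FormatError("voxel_size must be 3 positive components")
        aff = np.diag(np.concatenate([vs, [1.0]]))
        return cls(np.asarray(data), aff)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape3(self) -> tuple:
        return tuple(self.data.shape[:3])

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T + inv[:3, 3]).squeeze()


@dataclass
class RoiMask:
    """Binary region-of-interest mask on a volume grid."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask '{self.label}' has values outside {{0,1}}")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def write_volume(v: Volume, path) -> None:
    data = v.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, v.affine), str(path))


def read_mask(path, label: str = "") -> RoiMask:
    vol = read_volume(path)
    return RoiMask(vol.data > 0.5, label or os.path.basename(str(path)))


def read_dwi(volume_path, bval_path, bvec_path):
    """Load a 4D DWI volume with its FSL-style gradient table.

    Returns ``(Volume, GradientTable)``.  The 4th dimension of the volume
    must equal the number of gradient-table entries.
    """
    vol = read_volume(volume_path)
    if vol.data.ndim != 4:
        raise FormatError(f"{volume_path}: expected 4D DWI, got {vol.data.ndim}D")
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T  # FSL three-row layout
    elif bvecs.shape == (3, 3):
        # ambiguous; FSL dialect stores one direction per column
        bvecs = bvecs.T
    n_frames = vol.data.shape[3]
    if n_frames != bvals.size:
        raise FormatError(
            f"DWI has {n_frames} frames but gradient table lists "
            f"{bvals.size} entries"
        )
    return vol, GradientTable(bvecs, bvals)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), gtab.bvals[None], fmt="%.6g")
    np.savetxt(str(bvec_path), gtab.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# streamlines

def write_streamlines(streamline_points, path, affine_to_rasmm=None) -> None:
    """Write streamlines (sequences of world-mm points) to TRK or text.

    ``.trk`` paths use the TRK track container; any other extension gets the
    plain-text fallback: one ``x y z`` line per point, blank line between
    streamlines.  An empty set produces a valid empty container.
    """
    path = str(path)
    sls = [np.asarray(s, dtype=np.float32).reshape(-1, 3) for s in streamline_points]
    if path.endswith(".trk"):
        tractogram = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
        trk = nib.streamlines.TrkFile(tractogram)
        trk.save(path)
    else:
        with open(path, "w") as fh:
            for k, s in enumerate(sls):
                if k:
                    fh.write("\n")
                for p in s:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_streamlines(path):
    """Read streamlines written by :func:`write_streamlines` (world mm)."""
    path = str(path)
    if path.endswith(".trk"):
        trk = nib.streamlines.load(path)
        return [np.asarray(s, dtype=np.float64) for s in trk.tractogram.streamlines]
    out, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if cur:
                    out.append(np.asarray(cur, dtype=np.float64))
                    cur = []
                continue
            cur.append([float(x) for x in line.split()])
    if cur:
        out.append(np.asarray(cur, dtype=np.float64))
    return out
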