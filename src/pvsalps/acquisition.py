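"""Diffusion-weighted acquisition container and NIfTI / FSL bval-bvec I/O.

The acquisition geometry emulated throughout the package is a clinical
1.5 T protocol: 2.5 mm isotropic spin-echo EPI, 25 gradient directions at
b = 1000 s/mm² acquired in both positive and negative polarity, plus 8
b = 0 volumes.  Positive/negative polarity pairs are kept as independent
measurements (they enter the tensor fit separately, never averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DiffusionAcquisition",
    "default_gradient_scheme",
    "load_dwi",
    "save_dwi",
    "read_affine",
    "write_affine",
]


@dataclass
class DiffusionAcquisition:
    """4-D diffusion signal with its gradient table.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, v)
        Non-negative signal intensities, one volume per gradient entry.
    bvals : ndarray, shape (v,)
        b-value per volume in s/mm².
    bvecs : ndarray, shape (v, 3)
        Unit gradient direction per volume (zero vector for b=0 volumes).
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform.
    mask : ndarray of bool, shape (x, y, z), optional
        Brain mask; voxels outside are not fitted.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        nvol = self.signal.shape[3]
        if self.bvals.shape[0] != nvol or self.bvecs.shape[0] != nvol:
            raise ValueError(
                f"gradient table length ({self.bvals.shape[0]} bvals, "
                f"{self.bvecs.shape[0]} bvecs) does not match {nvol} volumes"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion gradient directions must be unit vectors")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


def default_gradient_scheme(
    n_directions: int = 25,
    b: float = 1000.0,
    n_b0: int = 8,
    polarity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic well-spread gradient table (bvals, bvecs).

    Directions are placed on a Fibonacci spiral over the upper hemisphere
    and, when ``polarity`` is set, emitted in both positive and negative
    polarity, doubling the direction count.  b=0 volumes come first.
    """
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions  # upper hemisphere, avoids poles/equator
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if polarity:
        dirs = np.vstack([dirs, -dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(dirs), b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def save_dwi(acq: DiffusionAcquisition, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.nii.gz`` plus FSL-dialect ``<prefix>.bval/.bvec``.

    The bvec file holds three rows (x, y, z components), one column per
    volume, matching the FSL convention.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(acq.signal.astype(np.float32), acq.affine), nii)
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    np.savetxt(bval, acq.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec, acq.bvecs.T, fmt="%.10g")
    paths = {"nii": nii, "bval": bval, "bvec": bvec}
    if acq.mask is not None:
        mask_path = prefix.parent / (prefix.name + "_mask.nii.gz")
        nib.save(
            nib.Nifti1Image(acq.mask.astype(np.uint8), acq.affine), mask_path
        )
        paths["mask"] = mask_path
    return paths


def load_dwi(
    nii: str | Path,
    bval: str | Path,
    bvec: str | Path,
    mask: str | Path | None = None,
) -> DiffusionAcquisition:
    """Load a NIfTI DWI with FSL-dialect bval/bvec text files."""
    img = nib.load(str(nii))
    bvals = np.loadtxt(bval).ravel()
    bvecs = np.loadtxt(bvec)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    mask_arr = None
    if mask is not None:
        mask_arr = np.asarray(nib.load(str(mask)).dataobj) > 0
    return DiffusionAcquisition(
        signal=np.asarray(img.dataobj, dtype=float),
        bvals=bvals,
        bvecs=bvecs,
        affine=img.affine,
        mask=mask_arr,
    )


def write_affine(affine: np.ndarray, path: str | Path) -> None:
    """Write a 4×4 affine as whitespace-delimited text (FSL .mat style)."""
    np.savetxt(path, np.asarray(affine, dtype=float).reshape(4, 4), fmt="%.10g")


def read_affine(path: str | Path) -> np.ndarray:
    aff = np.loadtxt(path)
    if aff.shape != (4, 4):
        raise ValueError(f"affine file {path} is not 4x4 (got {aff.shape})")
    return aff
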