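"""Per-voxel diffusion tensor fitting and derived scalar/directional maps.

The tensor is fitted by log-linear least squares: for signals S_i acquired
with b-value b_i and unit direction g_i, the model

    ln S_i = ln S0 − b_i · gᵢᵀ D gᵢ

is linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) and solved per voxel by
ordinary least squares.  This matches the default behaviour of the common
command-line tensor-fit tools and admits exact closed-form oracles on
noiseless phantoms.

Maps derived from the tensor: the directional diffusivities Dxx, Dyy, Dzz
(tensor diagonal in image axes — left–right, anterior–posterior,
inferior–superior after reorientation to RAS), fractional anisotropy (FA),
mean diffusivity (MD) and the principal eigenvector (V1).  Negative third
eigenvalues are never clamped; the affected voxels are flagged so that
downstream ROI QC can report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from pvsalps.acquisition import DiffusionAcquisition

__all__ = [
    "TensorField",
    "DiffusivityMaps",
    "fit_tensor",
    "derive_maps",
    "median_md",
    "psmd",
    "save_maps",
]

# column order of the 6 unique tensor components
_COMP = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with eigendecomposition.

    ``tensor`` holds the full 3×3 symmetric matrix per voxel (mm²/s);
    ``evals`` are sorted descending λ1 ≥ λ2 ≥ λ3 with matching unit
    eigenvectors in ``evecs`` (``evecs[..., :, k]`` pairs with
    ``evals[..., k]``).  ``valid`` marks voxels that were actually fitted;
    ``floored`` counts, per voxel, measurements raised to the signal floor
    before the log transform.
    """

    tensor: np.ndarray  # (x, y, z, 3, 3)
    evals: np.ndarray  # (x, y, z, 3) descending
    evecs: np.ndarray  # (x, y, z, 3, 3) columns = eigenvectors
    valid: np.ndarray  # (x, y, z) bool
    s0: np.ndarray  # (x, y, z) fitted S0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    floored: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]


@dataclass
class DiffusivityMaps:
    """Scalar and directional maps derived from a tensor field.

    Dxx/Dyy/Dzz are the tensor diagonal entries in image axes (mm²/s),
    FA is unitless in [0, 1], MD = (λ1+λ2+λ3)/3 (mm²/s) and V1 is the
    principal eigenvector.  ``negative_eval`` flags voxels with λ3 < 0.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    v1: np.ndarray  # (x, y, z, 3)
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    negative_eval: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dxx.shape


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows: [1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_tensor(
    acq: DiffusionAcquisition,
    signal_floor_rel: float = 1e-6,
) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    Parameters
    ----------
    acq : DiffusionAcquisition
        Must contain at least one b=0 volume and six non-collinear
        diffusion directions (checked through the design-matrix rank).
    signal_floor_rel : float
        Signals ≤ 0 (or below this fraction of the voxel's mean b=0
        signal) are raised to ``signal_floor_rel * S0`` before the log
        transform, so degenerate measurements cannot produce −inf.
        Floored measurements are counted per voxel in ``floored``.

    Returns
    -------
    TensorField
        Voxels with no usable b=0 signal are marked invalid, not fitted.
    """
    X = _design_matrix(acq.bvals, acq.bvecs)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        n_dirs = len(np.unique(np.round(acq.bvecs[acq.bvals > 0], 6), axis=0))
        raise ValueError(
            f"design matrix rank {rank} < 7: need at least 6 non-collinear "
            f"diffusion directions plus b=0 (got {n_dirs} unique directions)"
        )

    shape = acq.shape
    nvox = int(np.prod(shape))
    sig = acq.signal.reshape(nvox, -1)

    mask = np.ones(shape, dtype=bool) if acq.mask is None else acq.mask.astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    s0_est = sig[:, acq.bvals == 0].mean(axis=1)
    valid = mask.ravel() & (s0_est > 0)

    floor = signal_floor_rel * s0_est[valid, None]
    s = sig[valid]
    floored = s < floor
    s = np.where(floored, np.broadcast_to(floor, s.shape), s)

    # shared design matrix across voxels: one pseudoinverse, one matmul
    beta = np.linalg.pinv(X) @ np.log(s).T  # (7, n_valid)

    tensor = np.zeros((nvox, 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:7]
    t = np.empty((beta.shape[1], 3, 3))
    t[:, 0, 0] = dxx
    t[:, 1, 1] = dyy
    t[:, 2, 2] = dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    tensor[valid] = t

    evals = np.zeros((nvox, 3))
    evecs = np.zeros((nvox, 3, 3))
    w, v = np.linalg.eigh(t)  # ascending
    evals[valid] = w[:, ::-1]
    evecs[valid] = v[:, :, ::-1]

    s0_fit = np.zeros(nvox)
    s0_fit[valid] = np.exp(beta[0])
    floored_count = np.zeros(nvox, dtype=int)
    floored_count[valid] = floored.sum(axis=1)

    return TensorField(
        tensor=tensor.reshape(*shape, 3, 3),
        evals=evals.reshape(*shape, 3),
        evecs=evecs.reshape(*shape, 3, 3),
        valid=valid.reshape(shape),
        s0=s0_fit.reshape(shape),
        affine=acq.affine,
        floored=floored_count.reshape(shape),
    )


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA = √(1/2)·√((λ1−λ2)² + (λ2−λ3)² + (λ1−λ3)²) / √(λ1²+λ2²+λ3²).

    Zero where the eigenvalue norm vanishes.  For symmetric positive
    semi-definite tensors the value lies in [0, 1].
    """
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
    num = np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * num / den
    return np.where(den > 0, fa, 0.0)


def derive_maps(t: TensorField) -> DiffusivityMaps:
    """Read Dxx/Dyy/Dzz off the tensor diagonal and derive FA, MD, V1.

    Assumes the field is already in a right–anterior–superior axis order
    so that x = left–right, y = anterior–posterior, z = inferior–superior
    (phantoms are generated that way; file loaders reorient on read).
    """
    dxx = t.tensor[..., 0, 0]
    dyy = t.tensor[..., 1, 1]
    dzz = t.tensor[..., 2, 2]
    md = t.evals.sum(axis=-1) / 3.0
    fa = np.where(t.valid, fractional_anisotropy(t.evals), 0.0)
    v1 = t.evecs[..., :, 0]
    negative = t.valid & (t.evals[..., 2] < 0)
    return DiffusivityMaps(
        dxx=dxx,
        dyy=dyy,
        dzz=dzz,
        fa=fa,
        md=md,
        v1=v1,
        valid=t.valid.copy(),
        affine=t.affine,
        negative_eval=negative,
    )


def median_md(maps: DiffusivityMaps, wm_mask: np.ndarray) -> float:
    """Median MD over white-matter voxels (histogram/median analysis).

    The WM mask is intersected with the validity mask; an empty
    intersection is an error.
    """
    sel = (np.asarray(wm_mask) > 0) & maps.valid
    if not sel.any():
        raise ValueError("WM mask does not intersect any valid voxel")
    return float(np.median(maps.md[sel]))


def psmd(maps: DiffusivityMaps, skeleton_mask: np.ndarray) -> float:
    """Peak width of skeletonized MD: p95 − p5 of MD on the skeleton.

    Simplified form: the skeleton mask is an input (skeletonization is
    upstream).  Percentiles use the linear-interpolation convention of
    ``numpy.percentile``.
    """
    sel = (np.asarray(skeleton_mask) > 0) & maps.valid
    if not sel.any():
        raise ValueError("skeleton mask does not intersect any valid voxel")
    vals = maps.md[sel]
    p5, p95 = np.percentile(vals, [5.0, 95.0])
    return float(p95 - p5)


def save_maps(maps: DiffusivityMaps, out_dir: str | Path, prefix: str = "dti") -> dict[str, Path]:
    """Write Dxx/Dyy/Dzz/FA/MD/V1 as NIfTI-1 with the map affine."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "Dxx": maps.dxx,
        "Dyy": maps.dyy,
        "Dzz": maps.dzz,
        "FA": maps.fa,
        "MD": maps.md,
        "V1": maps.v1,
    }
    paths: dict[str, Path] = {}
    for name, arr in arrays.items():
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), maps.affine), p)
        paths[name] = p
    return paths
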