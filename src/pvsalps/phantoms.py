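"""Synthetic DWI and tissue-map phantoms with known ground truth.

Three generators feed the test surface of the imaging pipeline:

* :func:`generate_dwi_phantom` — piecewise-constant tensor fields turned
  into diffusion-weighted signal via the monoexponential tensor model
  S = S0·exp(−b·gᵀDg), optionally with Rician noise (the magnitude-MRI
  noise convention).  Default geometry mirrors the emulated acquisition:
  2.5 mm isotropic, 25 directions at b = 1000 s/mm² in positive and
  negative polarity, 8 b = 0 volumes.
* :func:`generate_alps_phantom` — plants axis-aligned anisotropic
  tensors at the four template-space ALPS ROI locations so the
  downstream index has a closed-form expected value (built directly in
  template space; no registration enters the test path).
* :func:`generate_tissue_phantom` — simple geometric tissue-class maps
  with planted PVS/lacune/ventricle structure and exact PVS voxel counts
  per region as ground truth.

None of this emulates realistic anatomy, partial volume, or motion/eddy
artifacts: the phantoms exercise the computations, not the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pvsalps.acquisition import DiffusionAcquisition, default_gradient_scheme
from pvsalps.alps import DEFAULT_ROI_CENTERS, AlpsROISet, build_roi_set
from pvsalps.pvs import TissueMaps

__all__ = [
    "Region",
    "PhantomSpec",
    "AlpsPhantom",
    "TissuePhantom",
    "generate_dwi_phantom",
    "generate_alps_phantom",
    "generate_tissue_phantom",
]

DEFAULT_S0 = 1000.0


@dataclass
class Region:
    """A named voxel set carrying one symmetric diffusion tensor (mm²/s)."""

    name: str
    mask: np.ndarray
    tensor: np.ndarray  # (3, 3) symmetric positive-definite

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (3, 3):
            raise ValueError(f"region {self.name!r}: tensor must be 3x3")
        if not np.allclose(self.tensor, self.tensor.T):
            raise ValueError(f"region {self.name!r}: tensor is not symmetric")
        if np.min(np.linalg.eigvalsh(self.tensor)) <= 0:
            raise ValueError(
                f"region {self.name!r}: tensor is not positive-definite"
            )


@dataclass
class PhantomSpec:
    """Geometry, tensors, gradient scheme and noise model of a phantom."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.5  # mm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # template mm of voxel 0
    regions: list[Region] = field(default_factory=list)
    background_tensor: np.ndarray = field(
        default_factory=lambda: np.diag([0.7e-3, 0.7e-3, 0.7e-3])
    )
    bvals: np.ndarray | None = None
    bvecs: np.ndarray | None = None
    n_b0: int = 8
    b: float = 1000.0
    n_directions: int = 25
    polarity: bool = True
    snr: float | None = None  # Rician SNR at S0; None = noiseless
    s0: float = DEFAULT_S0
    seed: int = 0

    def gradient_table(self) -> tuple[np.ndarray, np.ndarray]:
        if self.bvals is not None and self.bvecs is not None:
            bvals = np.asarray(self.bvals, dtype=float)
            bvecs = np.asarray(self.bvecs, dtype=float)
        else:
            bvals, bvecs = default_gradient_scheme(
                self.n_directions, self.b, self.n_b0, self.polarity
            )
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if dwi.any() and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("gradient directions must have unit norm (1e-9)")
        return bvals, bvecs

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        aff[:3, 3] = self.origin
        return aff


def _tensor_field(spec: PhantomSpec) -> np.ndarray:
    bg = np.asarray(spec.background_tensor, dtype=float)
    if np.min(np.linalg.eigvalsh(bg)) <= 0:
        raise ValueError("background tensor is not positive-definite")
    field_ = np.broadcast_to(bg, (*spec.shape, 3, 3)).copy()
    for region in spec.regions:
        if region.mask.shape != spec.shape:
            raise ValueError(
                f"region {region.name!r}: mask shape {region.mask.shape} "
                f"does not match grid {spec.shape}"
            )
        field_[region.mask] = region.tensor
    return field_


def generate_dwi_phantom(
    spec: PhantomSpec,
) -> tuple[DiffusionAcquisition, np.ndarray]:
    """Simulate DWI signal from a piecewise-constant tensor field.

    Returns the acquisition and the exact per-voxel tensor field used
    (shape ``(*grid, 3, 3)``, mm²/s).  Noise, when requested, is Rician:
    the magnitude of the complex signal after adding independent
    Gaussian noise of SD = S0/SNR to both channels.  Same seed ⇒
    bit-identical output.
    """
    bvals, bvecs = spec.gradient_table()
    tensors = _tensor_field(spec)
    # quadratic form b · gᵀ D g per voxel and volume
    quad = np.einsum("vi,...ij,vj->...v", bvecs, tensors, bvecs)
    signal = spec.s0 * np.exp(-bvals * quad)
    if spec.snr is not None:
        if spec.snr <= 0:
            raise ValueError("SNR must be positive")
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(real, imag)
    acq = DiffusionAcquisition(
        signal=signal, bvals=bvals, bvecs=bvecs, affine=spec.affine
    )
    return acq, tensors


@dataclass
class AlpsPhantom:
    """ALPS closed-form phantom: acquisition, ROI set and planted truth."""

    acquisition: DiffusionAcquisition
    rois: AlpsROISet
    tensor_field: np.ndarray
    expected: dict[str, float]  # planted-arithmetic left/right/mean indices


def _sphere_mask(
    shape: tuple[int, int, int],
    origin: np.ndarray,
    voxel_size: float,
    center: np.ndarray,
    radius: float,
) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    world = np.stack([ii, jj, kk], axis=-1) * voxel_size + origin
    return np.sum((world - center) ** 2, axis=-1) <= radius**2


def generate_alps_phantom(
    dxx_proj: float,
    dxx_assoc: float,
    dyy_proj: float,
    dzz_assoc: float,
    dxx_proj_left: float | None = None,
    dxx_assoc_left: float | None = None,
    dyy_proj_left: float | None = None,
    dzz_assoc_left: float | None = None,
    region_radius: float = 4.9,
    roi_diameter: float = 6.0,
    snr: float | None = None,
    seed: int = 0,
) -> AlpsPhantom:
    """Plant anisotropic tensors at the four ALPS ROI locations.

    Projection ROIs carry diag(dxx_proj, dyy_proj, d_fill) with the
    dominant eigenvector along the inferior–superior z axis; association
    ROIs carry diag(dxx_assoc, d_fill, dzz_assoc) dominant along
    anterior–posterior y (d_fill is set above every planted diffusivity).
    Left-side diffusivities default to the right-side values; pass the
    ``*_left`` arguments for an asymmetric phantom.

    The phantom lives directly in template space on a 1 mm grid with an
    integer-mm translation affine, so template sampling points coincide
    with voxel centers and the downstream index equals the planted
    arithmetic (Dxx_proj + Dxx_assoc)/(Dyy_proj + Dzz_assoc) exactly for
    noiseless phantoms.

    Raises
    ------
    ValueError
        For non-positive diffusivities or if the planted regions of
        neighbouring ROIs would overlap (possible only if the diameter
        or region radius is overridden in config).
    """
    right = (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
    left = (
        dxx_proj if dxx_proj_left is None else dxx_proj_left,
        dxx_assoc if dxx_assoc_left is None else dxx_assoc_left,
        dyy_proj if dyy_proj_left is None else dyy_proj_left,
        dzz_assoc if dzz_assoc_left is None else dzz_assoc_left,
    )
    vals = right + left
    if min(vals) <= 0:
        raise ValueError("all planted diffusivities must be positive")
    d_fill = 1.4 * max(vals) + 1e-4  # dominant axis, strictly above the rest

    rois = build_roi_set(DEFAULT_ROI_CENTERS, diameter=roi_diameter)
    centers = np.array([r.center for r in rois])
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 2 * region_radius:
                raise ValueError(
                    "planted ROI regions overlap: reduce region_radius or "
                    "restore default ROI geometry"
                )

    shape = (97, 41, 33)
    origin = np.array([-48.0, -32.0, 8.0])
    spec = PhantomSpec(
        shape=shape,
        voxel_size=1.0,
        origin=tuple(origin),
        snr=snr,
        seed=seed,
    )
    regions = []
    for side, (dxp, dxa, dyp, dza) in (("right", right), ("left", left)):
        proj = rois.get(side, "projection")
        assoc = rois.get(side, "association")
        regions.append(
            Region(
                f"{side}_projection",
                _sphere_mask(shape, origin, 1.0, np.array(proj.center), region_radius),
                np.diag([dxp, dyp, d_fill]),
            )
        )
        regions.append(
            Region(
                f"{side}_association",
                _sphere_mask(
                    shape, origin, 1.0, np.array(assoc.center), region_radius
                ),
                np.diag([dxa, d_fill, dza]),
            )
        )
    spec.regions = regions
    acq, tensors = generate_dwi_phantom(spec)

    def _index(v: tuple[float, float, float, float]) -> float:
        return (v[0] + v[1]) / (v[2] + v[3])

    expected = {
        "right": _index(right),
        "left": _index(left),
        "mean": 0.5 * (_index(right) + _index(left)),
    }
    return AlpsPhantom(
        acquisition=acq, rois=rois, tensor_field=tensors, expected=expected
    )


@dataclass
class TissuePhantom:
    """Tissue-class maps plus exact planted PVS counts per region."""

    maps: TissueMaps
    truth: dict[str, int]  # pvs_wb / pvs_bg / pvs_wm voxel counts


def generate_tissue_phantom(
    shape: tuple[int, int, int] = (30, 30, 30),
    voxel_size: float = 1.1,
    n_pvs_wm: int = 60,
    n_pvs_bg: int = 20,
    n_pvs_in_ventricle: int = 0,
    n_lacune_voxels: int = 12,
    extra_pvs: np.ndarray | None = None,
    seed: int = 0,
) -> TissuePhantom:
    """Geometric tissue maps with planted PVS structure.

    Brain = a central box; ventricles = a small central box (CSF);
    BG = two boxes flanking the ventricles; vessel CSF = the inferior
    slab of the brain's CSF rim; remaining brain = WM core + GM shell.
    PVS voxels are planted at seeded random positions inside WM and BG
    (CSF-class voxels by construction).  ``n_pvs_in_ventricle`` plants
    PVS inside the ventricle mask: such voxels are removed by the
    subtraction procedure and are *excluded* from the ground truth.

    Ground truth: exact planted PVS voxel counts for whole brain, BG and
    WM.  Planting PVS outside the brain mask raises an error.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    if min(shape) < 16:
        raise ValueError("phantom grid must be at least 16 voxels per axis")
    idx = np.indices(shape)

    brain = (
        (idx[0] >= 2) & (idx[0] < nx - 2)
        & (idx[1] >= 2) & (idx[1] < ny - 2)
        & (idx[2] >= 2) & (idx[2] < nz - 2)
    )
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    ventricles = (
        (abs(idx[0] - cx) <= 1) & (abs(idx[1] - cy) <= 2) & (abs(idx[2] - cz) <= 1)
    )
    bg = (
        (abs(idx[0] - cx) >= 3) & (abs(idx[0] - cx) <= 5)
        & (abs(idx[1] - cy) <= 3) & (abs(idx[2] - cz) <= 2)
        & brain
    )
    shell = brain & ~(
        (idx[0] >= 4) & (idx[0] < nx - 4)
        & (idx[1] >= 4) & (idx[1] < ny - 4)
        & (idx[2] >= 4) & (idx[2] < nz - 4)
    )
    vessel_csf = shell & (idx[2] < 5)
    gm = shell & ~vessel_csf
    wm = brain & ~gm & ~vessel_csf & ~ventricles & ~bg

    lacunes = np.zeros(shape, dtype=bool)
    wm_flat = np.flatnonzero(wm)
    if n_lacune_voxels > 0:
        pick = rng.choice(wm_flat, size=n_lacune_voxels, replace=False)
        lacunes.flat[pick] = True

    wmh = np.zeros(shape, dtype=bool)
    wmh_candidates = np.flatnonzero(wm & ~lacunes)
    wmh.flat[rng.choice(wmh_candidates, size=min(40, wmh_candidates.size), replace=False)] = True

    csf = ventricles | vessel_csf
    pvs_truth = np.zeros(shape, dtype=bool)

    def _plant(region_mask: np.ndarray, n: int, label: str) -> np.ndarray:
        if n == 0:
            return np.zeros(shape, dtype=bool)
        candidates = np.flatnonzero(region_mask & ~lacunes & ~csf & ~pvs_truth)
        if candidates.size < n:
            raise ValueError(f"not enough {label} voxels to plant {n} PVS")
        chosen = rng.choice(candidates, size=n, replace=False)
        planted = np.zeros(shape, dtype=bool)
        planted.flat[chosen] = True
        if np.any(planted & ~brain):
            raise ValueError(f"planted PVS outside brain mask in {label}")
        return planted

    pvs_wm = _plant(wm, n_pvs_wm, "WM")
    pvs_truth |= pvs_wm
    pvs_bg = _plant(bg, n_pvs_bg, "BG")
    pvs_truth |= pvs_bg
    if extra_pvs is not None:
        extra_pvs = np.asarray(extra_pvs).astype(bool)
        if extra_pvs.shape != shape:
            raise ValueError("extra_pvs mask shape does not match the grid")
        outside = extra_pvs & ~brain
        if outside.any():
            raise ValueError(
                f"{int(outside.sum())} planted PVS voxels lie outside the "
                "brain mask"
            )
        pvs_truth |= extra_pvs & ~lacunes & ~ventricles & ~vessel_csf
    csf = csf | pvs_truth

    if n_pvs_in_ventricle > 0:
        vent_flat = np.flatnonzero(ventricles)
        if vent_flat.size < n_pvs_in_ventricle:
            raise ValueError("ventricle too small for requested in-ventricle PVS")
        # inside the ventricle mask these are subtracted downstream, so
        # they never enter the ground-truth counts
        csf.flat[rng.choice(vent_flat, size=n_pvs_in_ventricle, replace=False)] = True

    maps = TissueMaps(
        gm=gm,
        wm=wm,
        csf=csf,
        wmh=wmh,
        lacunes=lacunes,
        ventricles=ventricles,
        vessel_csf=vessel_csf,
        bg=bg,
        voxel_volume=float(voxel_size**3),
    )
    truth = {
        "pvs_wb": int(pvs_truth.sum()),
        "pvs_bg": int((pvs_truth & bg).sum()),
        "pvs_wm": int((pvs_truth & wm).sum()),
    }
    return TissuePhantom(maps=maps, truth=truth)
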