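"""DTI-ALPS index: template-space ROI placement and index computation.

The index quantifies diffusion along perivascular spaces of the medullary
veins at the level of the lateral-ventricle body.  Four 6-mm-diameter
spherical ROIs are placed in MNI template space — on each side one in the
projection-fiber area (corona radiata, fibers along the inferior–superior
z axis, the medial ROI) and one in the association-fiber area (superior
longitudinal fasciculus, fibers along the anterior–posterior y axis, the
lateral ROI).  Per side,

    ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)

with Dxx/Dyy/Dzz the ROI means of the directional diffusivity maps, and
the reported index is the mean of the left and right sides.  A value of 1
means no preferential diffusion along the perivascular (x) axis; higher
values indicate better presumed perivascular/glymphatic function.

ROI means are taken on maps sampled into template space (1 mm grid inside
each sphere, trilinear interpolation), following the registration
direction of the reference workflow (individual maps registered to the
template).  Rasterization is voxel-center-in-sphere: deterministic and
checkable against brute-force enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from pvsalps.tensor import DiffusivityMaps, TensorField

__all__ = [
    "AlpsROI",
    "AlpsROISet",
    "AlpsResult",
    "DEFAULT_ROI_CENTERS",
    "build_roi_set",
    "rasterize_roi",
    "compute_alps",
    "roi_orientation_qc",
]

#: MNI-space centers (mm): right-projection, left-projection,
#: right-association, left-association.
DEFAULT_ROI_CENTERS: tuple[tuple[float, float, float], ...] = (
    (24.0, -12.0, 24.0),
    (-28.0, -12.0, 24.0),
    (36.0, -12.0, 24.0),
    (-40.0, -12.0, 24.0),
)

#: expected dominant-eigenvector axis per fiber role (image axis index)
ROLE_AXIS = {"projection": 2, "association": 1}


@dataclass(frozen=True)
class AlpsROI:
    """One spherical ROI: template-mm center, diameter, side and role."""

    center: tuple[float, float, float]
    side: str  # "left" | "right"
    role: str  # "projection" | "association"
    diameter: float = 6.0

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class AlpsROISet:
    rois: tuple[AlpsROI, ...]

    def get(self, side: str, role: str) -> AlpsROI:
        for roi in self.rois:
            if roi.side == side and roi.role == role:
                return roi
        raise KeyError(f"no ROI with side={side!r}, role={role!r}")

    def __iter__(self):
        return iter(self.rois)


@dataclass
class AlpsResult:
    """Per-side ROI diffusivity means, the three indices and QC."""

    roi_means: dict[str, dict[str, float]]  # e.g. {"right": {"dxx_proj": ...}}
    left: float
    right: float
    mean: float
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "left": self.left,
            "right": self.right,
            "mean": self.mean,
            "roi_means": self.roi_means,
            "qc": self.qc,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def build_roi_set(
    centers: tuple[tuple[float, float, float], ...] = DEFAULT_ROI_CENTERS,
    diameter: float = 6.0,
) -> AlpsROISet:
    """Label ROI centers by side (sign of x) and role (|x| ordering).

    Within a side the medial sphere (smaller |x|) is the projection ROI
    (corona radiata lies medial to the superior longitudinal fasciculus).
    Exactly two centers per side are required, with distinct |x|.
    """
    rois: list[AlpsROI] = []
    for side, sign in (("right", 1.0), ("left", -1.0)):
        side_centers = [c for c in centers if np.sign(c[0]) == sign]
        if len(side_centers) != 2:
            raise ValueError(
                f"expected exactly 2 ROI centers on the {side} side, "
                f"got {len(side_centers)}"
            )
        side_centers.sort(key=lambda c: abs(c[0]))
        if abs(side_centers[0][0]) == abs(side_centers[1][0]):
            raise ValueError(
                f"duplicated |x| on the {side} side: cannot assign "
                "projection/association roles"
            )
        rois.append(AlpsROI(tuple(side_centers[0]), side, "projection", diameter))
        rois.append(AlpsROI(tuple(side_centers[1]), side, "association", diameter))
    return AlpsROISet(tuple(rois))


def rasterize_roi(
    roi: AlpsROI, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean voxel mask: voxel centers within the ROI radius.

    ``affine`` maps voxel indices of the target grid to the template mm
    space the ROI center lives in.  No partial volumes: a voxel is in or
    out by its center.
    """
    affine = np.asarray(affine, dtype=float)
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((world - np.asarray(roi.center)) ** 2, axis=1)
    mask = (d2 <= roi.radius**2).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"ROI {roi.side}/{roi.role} at {roi.center} lies entirely "
            "outside the target grid"
        )
    return mask


def _template_points(roi: AlpsROI, spacing: float = 1.0) -> np.ndarray:
    """Integer-spaced template-mm sample points inside the sphere."""
    c = np.asarray(roi.center)
    r = roi.radius
    axes = [
        np.arange(np.ceil((c[a] - r) / spacing), np.floor((c[a] + r) / spacing) + 1)
        * spacing
        for a in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.sum((pts - c) ** 2, axis=1) <= r**2
    return pts[keep]


def _sample(volume: np.ndarray, vox_coords: np.ndarray, order: int) -> np.ndarray:
    return map_coordinates(
        np.asarray(volume, dtype=float),
        vox_coords.T,
        order=order,
        mode="constant",
        cval=np.nan,
    )


def compute_alps(
    maps: DiffusivityMaps,
    rois: AlpsROISet | None = None,
    map_to_template: np.ndarray | None = None,
    sample_spacing: float = 1.0,
    orientation_threshold: float = 0.5,
) -> AlpsResult:
    """Compute left, right and mean DTI-ALPS with QC.

    Parameters
    ----------
    maps : DiffusivityMaps
        Directional diffusivity maps with a voxel→world affine.
    rois : AlpsROISet, optional
        Defaults to the four standard template-space spheres.
    map_to_template : ndarray (4, 4), optional
        Affine taking the map's world space into template space
        (identity for maps already in template space, e.g. phantoms).
    sample_spacing : float
        Spacing (mm) of the template-space sampling grid inside each
        sphere; values are pulled from the maps by trilinear
        interpolation, validity by nearest neighbour.
    orientation_threshold : float
        Minimum fraction of ROI voxels whose principal eigenvector is
        dominant along the expected axis before a warning is flagged.

    Raises
    ------
    ValueError
        If an ROI captures no valid voxel, or a side's denominator
        (Dyy_proj + Dzz_assoc) is not positive.
    """
    if rois is None:
        rois = build_roi_set()
    total = np.asarray(
        map_to_template if map_to_template is not None else np.eye(4)
    ) @ np.asarray(maps.affine)
    inv = np.linalg.inv(total)

    roi_means: dict[str, dict[str, float]] = {"left": {}, "right": {}}
    qc: dict[str, dict] = {}
    valid_f = maps.valid.astype(float)
    for roi in rois:
        pts = _template_points(roi, sample_spacing)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        val = _sample(valid_f, vox, order=0)
        ok = np.isfinite(val) & (val > 0.5)
        n_total, n_ok = len(pts), int(ok.sum())
        if n_ok == 0:
            raise ValueError(
                f"ROI {roi.side}/{roi.role} at {roi.center} captures no "
                "valid voxel"
            )
        means = {}
        for name, vol in (("dxx", maps.dxx), ("dyy", maps.dyy), ("dzz", maps.dzz)):
            means[name] = float(np.mean(_sample(vol, vox[ok], order=1)))
        suffix = "proj" if roi.role == "projection" else "assoc"
        side = roi_means[roi.side]
        side[f"dxx_{suffix}"] = means["dxx"]
        if roi.role == "projection":
            side["dyy_proj"] = means["dyy"]
        else:
            side["dzz_assoc"] = means["dzz"]

        entry = {
            "n_samples": n_total,
            "n_valid": n_ok,
            "n_invalid": n_total - n_ok,
        }
        if maps.negative_eval is not None:
            neg = _sample(maps.negative_eval.astype(float), vox[ok], order=0)
            entry["n_negative_eigenvalue"] = int(np.nansum(neg > 0.5))
        if maps.v1 is not None:
            v1 = np.stack(
                [_sample(maps.v1[..., a], vox[ok], order=0) for a in range(3)],
                axis=-1,
            )
            dominant = np.argmax(np.abs(v1), axis=-1)
            frac = float(np.mean(dominant == ROLE_AXIS[roi.role]))
            entry["orientation_fraction"] = frac
            entry["orientation_warn"] = bool(frac < orientation_threshold)
        qc[f"{roi.side}_{roi.role}"] = entry

    indices = {}
    for side in ("left", "right"):
        m = roi_means[side]
        num = m["dxx_proj"] + m["dxx_assoc"]
        den = m["dyy_proj"] + m["dzz_assoc"]
        if den <= 0:
            raise ValueError(
                f"{side} denominator Dyy_proj + Dzz_assoc = {den:g} is not "
                "positive: non-physical diffusivities"
            )
        indices[side] = num / den
    return AlpsResult(
        roi_means=roi_means,
        left=indices["left"],
        right=indices["right"],
        mean=0.5 * (indices["left"] + indices["right"]),
        qc=qc,
    )


def roi_orientation_qc(
    t: TensorField,
    rois: AlpsROISet | None = None,
    map_to_template: np.ndarray | None = None,
    threshold: float = 0.5,
) -> dict[str, dict]:
    """Automated surrogate for the visual fiber-direction ROI check.

    For each ROI (rasterized on the tensor grid), reports the fraction of
    voxels whose principal eigenvector has its largest absolute component
    along the expected axis — z for projection, y for association — and a
    warn flag when the fraction falls below ``threshold``.  Advisory
    only: ROIs are never moved.
    """
    if rois is None:
        rois = build_roi_set()
    total = np.asarray(
        map_to_template if map_to_template is not None else np.eye(4)
    ) @ np.asarray(t.affine)
    out: dict[str, dict] = {}
    for roi in rois:
        mask = rasterize_roi(roi, total, t.shape) & t.valid
        key = f"{roi.side}_{roi.role}"
        if not mask.any():
            out[key] = {"n_voxels": 0, "fraction": np.nan, "warn": True}
            continue
        v1 = t.evecs[mask][:, :, 0]
        dominant = np.argmax(np.abs(v1), axis=-1)
        frac = float(np.mean(dominant == ROLE_AXIS[roi.role]))
        out[key] = {
            "n_voxels": int(mask.sum()),
            "fraction": frac,
            "warn": bool(frac < threshold),
        }
    return out
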