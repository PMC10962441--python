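"""Perivascular-space maps and volumetry from tissue-class maps.

PVS voxels share the signal characteristics of CSF, so the PVS map is
obtained by set subtraction from the CSF tissue class: remove the
ventricles, manually identified lacunes, and the CSF surrounding large
vessels / outside the brain (supplied as an explicit exclusion mask —
in the reference workflow this step was manual).  Volumes are voxel
counts × voxel volume, reported for the whole brain and within the basal
ganglia (BG) and white matter (WM) masks, normalized by total brain
volume (GM volume + WM volume) and natural-log transformed.

No size or shape filtering of PVS candidates is applied: the procedure
is purely subtractive, with an optional review mask standing in for the
manual inspection step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueMaps",
    "PvsVolumes",
    "make_pvs_map",
    "pvs_volumes",
    "reliability_report",
]


@dataclass
class TissueMaps:
    """Binary tissue-class masks on a common grid.

    All masks are boolean arrays of identical shape; ``voxel_volume``
    is in mm³.  Whether ventricles ⊆ CSF is checked and reported by
    :meth:`consistency`, not enforced.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    wmh: np.ndarray
    lacunes: np.ndarray
    ventricles: np.ndarray
    vessel_csf: np.ndarray  # extra-cerebral / large-vessel CSF exclusion
    bg: np.ndarray
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        ref = None
        for name in (
            "gm",
            "wm",
            "csf",
            "wmh",
            "lacunes",
            "ventricles",
            "vessel_csf",
            "bg",
        ):
            arr = np.asarray(getattr(self, name))
            if arr.dtype != bool:
                uniq = np.unique(arr)
                if not np.all(np.isin(uniq, (0, 1))):
                    raise ValueError(f"mask {name!r} is not binary")
                arr = arr.astype(bool)
            if ref is None:
                ref = (name, arr.shape)
            elif arr.shape != ref[1]:
                raise ValueError(
                    f"grid mismatch: {name!r} has shape {arr.shape}, "
                    f"{ref[0]!r} has {ref[1]}"
                )
            setattr(self, name, arr)
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    @property
    def brain(self) -> np.ndarray:
        return self.gm | self.wm

    def consistency(self) -> dict[str, int]:
        """Report (not enforce) expected containments."""
        return {
            "ventricle_voxels_outside_csf": int((self.ventricles & ~self.csf).sum()),
            "lacune_voxels_outside_brain": int((self.lacunes & ~self.brain).sum()),
        }


@dataclass
class PvsVolumes:
    """Raw (mm³), normalized (ratio to brain volume) and log volumes.

    ``log_*`` is the natural log of the normalized volume; NaN where the
    raw regional volume is zero (the log is undefined there — downstream
    models must handle such subjects explicitly, no pseudo-count is
    added).
    """

    raw_wb: float
    raw_bg: float
    raw_wm: float
    brain_volume: float
    norm_wb: float
    norm_bg: float
    norm_wm: float
    log_wb: float
    log_bg: float
    log_wm: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def make_pvs_map(t: TissueMaps, review_mask: np.ndarray | None = None) -> np.ndarray:
    """PVS map = CSF ∖ (lacunes ∪ ventricles ∪ vessel/extra-cerebral CSF).

    Union semantics: a voxel in several exclusion masks is removed once.
    ``review_mask``, when given, additionally removes voxels rejected by
    manual review.  An empty CSF map yields an empty PVS map with a
    warning.
    """
    if not t.csf.any():
        warnings.warn("CSF map is empty: PVS map will be empty", stacklevel=2)
    exclusion = t.lacunes | t.ventricles | t.vessel_csf
    pvs = t.csf & ~exclusion
    if review_mask is not None:
        review_mask = np.asarray(review_mask).astype(bool)
        if review_mask.shape != pvs.shape:
            raise ValueError("grid mismatch: review_mask shape differs from CSF map")
        pvs &= ~review_mask
    return pvs


def pvs_volumes(pvs: np.ndarray, t: TissueMaps, log: bool = True) -> PvsVolumes:
    """Regional PVS volumes, normalized by brain volume, log-transformed.

    Regional volume = |PVS ∩ region mask| × voxel volume; brain volume =
    (GM + WM voxel count) × voxel volume.  Requesting the log transform
    with zero whole-brain PVS volume is an error; a zero subregion gives
    NaN for that region's log.
    """
    pvs = np.asarray(pvs).astype(bool)
    if pvs.shape != t.csf.shape:
        raise ValueError("grid mismatch: PVS map shape differs from tissue maps")
    vv = t.voxel_volume
    raw_wb = float(pvs.sum() * vv)
    raw_bg = float((pvs & t.bg).sum() * vv)
    raw_wm = float((pvs & t.wm).sum() * vv)
    brain_volume = float(t.brain.sum() * vv)
    if brain_volume <= 0:
        raise ValueError("brain volume (GM + WM) is zero")
    if log and raw_wb == 0:
        raise ValueError(
            "whole-brain PVS volume is zero: log transform undefined "
            "(pass log=False to get raw/normalized volumes)"
        )

    def _norm(raw: float) -> float:
        return raw / brain_volume

    def _log(raw: float) -> float:
        if not log or raw <= 0:
            return math.nan
        return math.log(raw / brain_volume)

    return PvsVolumes(
        raw_wb=raw_wb,
        raw_bg=raw_bg,
        raw_wm=raw_wm,
        brain_volume=brain_volume,
        norm_wb=_norm(raw_wb),
        norm_bg=_norm(raw_bg),
        norm_wm=_norm(raw_wm),
        log_wb=_log(raw_wb),
        log_bg=_log(raw_bg),
        log_wm=_log(raw_wm),
    )


def reliability_report(
    volumes_a: np.ndarray, volumes_b: np.ndarray
) -> dict[str, float]:
    """Interrater agreement over paired volume measurements.

    Returns SEM (SD of paired differences / √2), mean percent variability
    (|ΔV| / pair mean × 100, averaged) and ICC(2,1) — two-way random
    effects, absolute agreement, single measurement:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with MSR/MSC/MSE the rows (subjects), columns (raters) and error mean
    squares of the two-way ANOVA, k = 2 raters, n pairs.
    """
    a = np.asarray(volumes_a, dtype=float).ravel()
    b = np.asarray(volumes_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired volume arrays must have equal length")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 paired observations, got {n}")
    diffs = a - b
    sem = float(np.std(diffs, ddof=1) / np.sqrt(2.0))
    pair_means = (a + b) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.abs(diffs) / pair_means * 100.0
    pct_var = float(np.nanmean(np.where(pair_means != 0, pct, 0.0)))

    k = 2
    data = np.column_stack([a, b])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return {"sem": sem, "percent_variability": pct_var, "icc": icc, "n_pairs": n}
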