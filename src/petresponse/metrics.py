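"""Per-lesion metabolic metrics at a single time point.

Six metrics are computed per lesion: SUVmax, SUVpeak (mean over the hottest
1 cm^3 spherical neighbourhood), SUVmean, metabolic volume (MV, mL), total
lesion glycolysis (TLG = SUVmean x MV) and standardized added metabolic
activity (SAM, the total uptake in excess of local background over an
enlarged region, designed to be insensitive to partial-volume and
delineation error).  Body-weight SUV is assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import SegmentationError
from .volume import LesionVOI, PETVolume

__all__ = [
    "LesionMetrics",
    "METRIC_NAMES",
    "suv_max",
    "suv_peak",
    "suv_mean_mv_tlg",
    "sam",
    "compute_all",
    "peak_sphere_offsets",
]

METRIC_NAMES = ("suv_max", "suv_peak", "suv_mean", "mv", "tlg", "sam")


@dataclass
class LesionMetrics:
    lesion_id: str
    frame_id: str
    suv_max: float
    suv_peak: float
    suv_mean: float
    mv: float        # mL
    tlg: float       # SUV * mL
    sam: float       # SUV * mL
    organ: str = "node"

    def __post_init__(self):
        vals = [self.suv_max, self.suv_peak, self.suv_mean, self.mv, self.tlg, self.sam]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all metric values must be finite")
        if self.mv < 0:
            raise ValueError("metabolic volume must be non-negative")
        if self.suv_peak > self.suv_max + 1e-9:
            raise ValueError("SUVpeak cannot exceed SUVmax")
        if abs(self.tlg - self.suv_mean * self.mv) > 1e-9 * max(1.0, abs(self.tlg)):
            raise ValueError("TLG must equal SUVmean x MV")

    def value(self, metric: str) -> float:
        return float(getattr(self, metric))


def _require_mask(voi: LesionVOI):
    if voi.mask.sum() < 1:
        raise ValueError("empty lesion mask")


def suv_max(volume: PETVolume, voi: LesionVOI) -> float:
    """Maximum voxel SUV within the lesion mask."""
    _require_mask(voi)
    return float(volume.values[voi.mask].max())


def peak_sphere_offsets(spacing, volume_ml: float = 1.0) -> np.ndarray:
    """Voxel-offset triples whose centers fall inside a sphere of the given
    volume (default 1 cm^3, diameter ~12.4 mm), on a grid with ``spacing``."""
    radius = (3.0 * 1000.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    sp = np.asarray(spacing, dtype=float)
    reach = np.floor(radius / sp).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = np.sum((grid * sp) ** 2, axis=1)
    offsets = grid[d2 <= radius**2]
    if len(offsets) == 0:
        offsets = np.zeros((1, 3), dtype=int)
    return offsets


def suv_peak(volume: PETVolume, voi: LesionVOI, sphere_volume_ml: float = 1.0) -> float:
    """Hottest mean SUV over a 1 cm^3 sphere centered on a mask voxel.

    The sphere is rasterized by voxel-center inclusion; it may extend beyond
    the mask but must fit inside the volume, so candidate centers too close to
    the border are skipped.
    """
    _require_mask(voi)
    offsets = peak_sphere_offsets(volume.spacing, sphere_volume_ml)
    reach = np.abs(offsets).max(axis=0)
    shape = np.asarray(volume.shape)
    if np.any(2 * reach + 1 > shape):
        raise ValueError("peak sphere larger than the volume")
    centers = np.argwhere(voi.mask)
    ok = np.all((centers >= reach) & (centers <= shape - 1 - reach), axis=1)
    centers = centers[ok]
    if len(centers) == 0:
        raise ValueError("no mask voxel admits a fully inside peak sphere")
    # gather sphere members for every candidate center at once
    idx = centers[:, None, :] + offsets[None, :, :]  # (n_centers, n_sphere, 3)
    means = volume.values[idx[..., 0], idx[..., 1], idx[..., 2]].mean(axis=1)
    return float(means.max())


def suv_mean_mv_tlg(volume: PETVolume, voi: LesionVOI):
    """(SUVmean over the mask, metabolic volume in mL, TLG = SUVmean x MV)."""
    _require_mask(voi)
    mean = float(volume.values[voi.mask].mean())
    mv = voi.n_voxels * volume.voxel_volume_ml
    return mean, mv, mean * mv


def sam(
    volume: PETVolume,
    voi: LesionVOI,
    margin_mm: float = 8.0,
    shell=(10.0, 20.0),
    bg_exclusion_frac: float = 0.4,
) -> float:
    """Standardized added metabolic activity over an enlarged VOI.

    The segmentation mask is dilated by ``margin_mm`` into region A; SAM is
    the integral of SUV over A minus the shell-background mean times Vol(A).
    Because the enlarged VOI captures activity smeared out of the lesion, SAM
    is insensitive to the exact delineation and to partial-volume losses.
    """
    _require_mask(voi)
    dist = ndimage.distance_transform_edt(~voi.mask, sampling=volume.spacing)
    enlarged = dist <= margin_mm
    inner, outer = shell
    shell_mask = (dist > margin_mm + inner) & (dist <= margin_mm + outer)
    if volume.validity is not None:
        shell_mask &= volume.validity
    if not shell_mask.any():
        raise SegmentationError("SAM background shell lies outside the grid")
    kept = shell_mask & (
        volume.values <= bg_exclusion_frac * float(volume.values[voi.mask].max())
    )
    # without focal contrast the exclusion removes everything; fall back to a
    # robust unexcluded estimate (SAM is then ~0 by construction)
    bg = float(volume.values[kept].mean()) if kept.any() else float(
        np.median(volume.values[shell_mask])
    )
    voxvol = volume.voxel_volume_ml
    total = float(volume.values[enlarged].sum()) * voxvol
    return total - bg * float(enlarged.sum()) * voxvol


def compute_all(
    volume: PETVolume,
    voi: LesionVOI,
    sphere_volume_ml: float = 1.0,
    sam_margin_mm: float = 8.0,
    sam_shell=(10.0, 20.0),
) -> LesionMetrics:
    """All six metrics for one lesion at one time point."""
    mean, mv, tlg = suv_mean_mv_tlg(volume, voi)
    return LesionMetrics(
        lesion_id=voi.lesion_id,
        frame_id=volume.frame_id,
        suv_max=suv_max(volume, voi),
        suv_peak=suv_peak(volume, voi, sphere_volume_ml),
        suv_mean=mean,
        mv=mv,
        tlg=tlg,
        sam=sam(volume, voi, sam_margin_mm, sam_shell),
        organ=voi.organ,
    )
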