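"""Core imaging data model: SUV volumes, rigid transforms, lesion VOIs, NIfTI I/O.

Coordinate convention: voxel indices are 0-based and axis-aligned;
``physical = origin + index * spacing`` (mm).  No oblique affines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "PETVolume",
    "RigidTransform",
    "LesionVOI",
    "ORGANS",
    "to_suv",
    "read_volume",
    "write_volume",
]

ORGANS = ("node", "bone", "liver", "breast", "lung", "peritoneum")

#: 26-connectivity structuring element used for every connected-component pass.
CONN26 = np.ones((3, 3, 3), dtype=bool)


def to_suv(concentration, weight_kg, injected_activity_mbq):
    """Body-weight SUV from activity concentration.

    Parameters
    ----------
    concentration : float or ndarray
        Activity concentration in kBq/mL.
    weight_kg : float
        Patient body weight in kg.
    injected_activity_mbq : float
        Injected activity at scan start, MBq (assumed already decay-corrected).

    Returns
    -------
    float or ndarray
        Dimensionless SUV = concentration / (injected activity / body mass),
        assuming 1 g of tissue occupies 1 mL.  In these units the conversion
        reduces to ``C * W / D``.
    """
    if weight_kg <= 0 or injected_activity_mbq <= 0:
        raise ValueError("weight and injected activity must be positive")
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc <= 0) if conc.ndim == 0 else np.any(conc < 0):
        raise ValueError("activity concentration must be positive")
    return concentration * weight_kg / injected_activity_mbq


@dataclass
class PETVolume:
    """A 3-D PET volume in SUV units with voxel-grid metadata.

    ``values[i, j, k]`` sits at physical position ``origin + (i, j, k) * spacing``.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    frame_id: str = ""
    acquisition_meta: dict | None = None
    validity: np.ndarray | None = None  # optional mask of valid voxels (resampling)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("PET volume must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_physical(self, index):
        idx = np.asarray(index, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_index(self, point):
        pt = np.asarray(point, dtype=float)
        return (pt - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def physical_center(self):
        return self.index_to_physical((np.asarray(self.shape) - 1) / 2.0)

    def with_values(self, values, frame_id=None, validity=None) -> "PETVolume":
        """Copy of this volume with new voxel data on the same grid."""
        return PETVolume(
            values=values,
            spacing=self.spacing,
            origin=self.origin,
            frame_id=self.frame_id if frame_id is None else frame_id,
            acquisition_meta=self.acquisition_meta,
            validity=validity,
        )

    def coordinate_grid(self):
        """Physical coordinates of every voxel center, shape ``shape + (3,)``."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclass
class RigidTransform:
    """Rigid body transform: rotation (xyz Euler, radians) about ``center`` plus
    a translation in mm.  ``apply(x) = R (x - c) + c + t``."""

    rotation: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.rotation = tuple(float(r) for r in self.rotation)
        self.translation = tuple(float(t) for t in self.translation)
        self.center = tuple(float(c) for c in self.center)
        if not all(
            np.all(np.isfinite(v)) for v in (self.rotation, self.translation, self.center)
        ):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=center)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    @classmethod
    def from_matrix(cls, rotation_matrix, translation, center=(0.0, 0.0, 0.0)):
        """Build from a rotation matrix and the translation of ``x -> Rx + t``."""
        rot = Rotation.from_matrix(rotation_matrix)
        c = np.asarray(center, dtype=float)
        # x -> R x + t_full  ==  R (x - c) + c + t  with  t = t_full + R c - c
        t = np.asarray(translation, dtype=float) + rotation_matrix @ c - c
        return cls(rotation=tuple(rot.as_euler("xyz")), translation=tuple(t), center=tuple(c))

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        t_inv = -R.T @ np.asarray(self.translation)
        rot = Rotation.from_matrix(R.T)
        return RigidTransform(
            rotation=tuple(rot.as_euler("xyz")),
            translation=tuple(t_inv),
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: the transform mapping ``x -> self(other(x))``,
        expressed about ``self.center``."""
        Ra, Rb = self.matrix, other.matrix
        ca = np.asarray(self.center)
        # full-form translations of x -> R x + t_full
        ta_full = np.asarray(self.translation) + ca - Ra @ ca
        cb = np.asarray(other.center)
        tb_full = np.asarray(other.translation) + cb - Rb @ cb
        R = Ra @ Rb
        t_full = Ra @ tb_full + ta_full
        return RigidTransform.from_matrix(R, t_full, center=self.center)

    @property
    def rotation_deg(self):
        return tuple(np.degrees(self.rotation))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "rotation_rad": list(self.rotation),
                "translation_mm": list(self.translation),
                "center_mm": list(self.center),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            rotation=tuple(d["rotation_rad"]),
            translation=tuple(d["translation_mm"]),
            center=tuple(d["center_mm"]),
        )


@dataclass
class LesionVOI:
    """A seeded, organ-labelled lesion region on a PET grid."""

    lesion_id: str
    organ: str
    seed: tuple
    mask: np.ndarray
    bounding_box: tuple = field(default=None)

    def __post_init__(self):
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}, got {self.organ!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.seed = tuple(int(s) for s in self.seed)
        if self.mask.ndim != 3 or self.mask.sum() < 1:
            raise ValueError("mask must be a non-empty 3-D boolean array")
        if not self.mask[self.seed]:
            raise ValueError("seed voxel must lie inside the mask")
        labels, n = ndimage.label(self.mask, structure=CONN26)
        if n != 1:
            raise ValueError("mask must be a single 26-connected component")
        if self.bounding_box is None:
            self.bounding_box = self._compute_bbox()
        elif self.bounding_box != self._compute_bbox():
            raise ValueError("bounding_box does not cover the mask exactly")

    def _compute_bbox(self):
        idx = np.nonzero(self.mask)
        return tuple((int(a.min()), int(a.max()) + 1) for a in idx)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path, units: str = "SUV", acquisition_meta: dict | None = None) -> PETVolume:
    """Read a 3-D NIfTI image as a :class:`PETVolume`.

    ``units="activity_concentration"`` converts voxel values (kBq/mL) to SUV,
    which requires ``acquisition_meta`` with ``weight_kg`` and
    ``injected_activity_mbq``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError("non-positive voxel spacing in header")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if units == "activity_concentration":
        if not acquisition_meta or not {"weight_kg", "injected_activity_mbq"} <= set(
            acquisition_meta
        ):
            raise ValueError(
                "activity-concentration input requires acquisition_meta with "
                "weight_kg and injected_activity_mbq"
            )
        data = data * acquisition_meta["weight_kg"] / acquisition_meta["injected_activity_mbq"]
    elif units != "SUV":
        raise ValueError(f"unknown units {units!r}")
    # optional JSON sidecar carries acquisition metadata
    sidecar = path.with_suffix("").with_suffix(".json")
    if acquisition_meta is None and sidecar.exists():
        acquisition_meta = json.loads(sidecar.read_text())
    return PETVolume(
        values=data,
        spacing=spacing,
        origin=origin,
        frame_id=path.stem,
        acquisition_meta=acquisition_meta,
    )


def write_volume(volume: PETVolume, path) -> None:
    """Write a volume as NIfTI-1 (float32, axis-aligned RAS affine)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    if volume.acquisition_meta:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(volume.acquisition_meta)
        )
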