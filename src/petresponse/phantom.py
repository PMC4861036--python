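"""Synthetic paired-scan phantoms with known lesion responses.

The generator emulates a baseline / follow-up pair of whole-body FDG PET
volumes: a uniform soft-tissue background, spherical focal lesions whose SUV
changes between the two time points, an isotropic Gaussian point-spread
function, additive Gaussian noise in SUV units, and a known rigid
misalignment of the follow-up frame.  Ground truth (true percent change of
mean lesion SUV, responder labels, the misalignment transform) is returned
alongside, standing in for the clinical gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ORGANS, PETVolume, RigidTransform, write_volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "Cohort",
    "generate_pair",
    "generate_cohort",
    "sample_catalog",
    "DEFAULT_RESPONSE_MIX",
]

#: Lesion response classes and the true mean-SUV percent-change band each draws
#: from.  The (-34, -26)% guard band around the -30% adjudication boundary
#: reflects that clinical gold standards do not label hairline evolutions.
RESPONSE_BANDS = {
    "responder": (-72.0, -34.0),
    "minor_decline": (-26.0, -8.0),
    "stable": (-5.0, 5.0),
    "progression": (15.0, 60.0),
}

DEFAULT_RESPONSE_MIX = {
    "responder": 0.50,
    "minor_decline": 0.10,
    "stable": 0.15,
    "progression": 0.25,
}

#: Organ sampling frequencies mirroring the studied lesion distribution
#: (nodes : bone : liver : breast : lung : peritoneum = 44:43:17:10:5:4).
ORGAN_FREQUENCIES = {
    "node": 44,
    "bone": 43,
    "liver": 17,
    "breast": 10,
    "lung": 5,
    "peritoneum": 4,
}

#: Default ground-truth response rule: responder iff true mean-SUV percent
#: change <= -30 (PERCIST-like), configurable on PhantomSpec.
RESPONSE_RULE_THRESHOLD = -30.0


@dataclass
class LesionSpec:
    """One spherical lesion: position/size in mm, SUV at both time points."""

    center: tuple
    radius: float
    suv_t1: float
    suv_t2: float
    organ: str = "node"
    radius_t2: float | None = None
    lesion_id: str = ""

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}")
        self.center = tuple(float(c) for c in self.center)

    @property
    def true_change_pct(self) -> float:
        """True percent change of the lesion's mean SUV (uniform sphere)."""
        return 100.0 * (self.suv_t2 - self.suv_t1) / self.suv_t1


@dataclass
class PhantomSpec:
    grid_shape: tuple = (96, 96, 96)
    spacing: tuple = (2.0, 2.0, 2.0)
    background_suv: float = 2.0
    lesions: list = field(default_factory=list)
    psf_fwhm: float = 6.0
    noise_sigma: float = 0.15
    misalignment: RigidTransform | None = None
    seed: int = 0
    response_rule_threshold: float = RESPONSE_RULE_THRESHOLD

    def __post_init__(self):
        if self.psf_fwhm < 0 or self.noise_sigma < 0:
            raise ValueError("psf_fwhm and noise_sigma must be non-negative")
        for les in self.lesions:
            if les.suv_t1 <= self.background_suv:
                raise ValueError(
                    f"lesion {les.lesion_id or les.center}: suv_t1 must exceed background"
                )

    @property
    def extent_mm(self):
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass
class GroundTruth:
    """Known truth for one phantom pair."""

    lesions: pd.DataFrame  # lesion_id, organ, true_change_pct, gold_label
    patient_label: str
    misalignment: RigidTransform
    response_rule_threshold: float = RESPONSE_RULE_THRESHOLD

    def lesion_label(self, lesion_id) -> str:
        row = self.lesions.set_index("lesion_id").loc[lesion_id]
        return str(row["gold_label"])


def _check_geometry(spec: PhantomSpec) -> None:
    lesions = spec.lesions
    for i, a in enumerate(lesions):
        for b in lesions[i + 1 :]:
            d = np.linalg.norm(np.subtract(a.center, b.center))
            if d <= a.radius + b.radius:
                raise ValueError(f"lesions {a.lesion_id!r} and {b.lesion_id!r} overlap")
    lo = np.zeros(3)
    hi = np.asarray(spec.extent_mm)
    mis = spec.misalignment or RigidTransform.identity()
    inv = mis.inverse()
    for les in lesions:
        r2 = les.radius_t2 if les.radius_t2 is not None else les.radius
        c1 = np.asarray(les.center)
        c2 = inv.apply(les.center)  # lesion center expressed in the follow-up grid
        for c, r in ((c1, les.radius), (c2, r2)):
            if np.any(c - r < lo) or np.any(c + r > hi):
                raise ValueError(
                    f"lesion {les.lesion_id!r} is clipped by the grid boundary"
                )


def _render_frame(spec: PhantomSpec, frame: int, transform: RigidTransform | None,
                  rng: np.random.Generator) -> np.ndarray:
    """Evaluate the analytic scene on the (possibly misaligned) grid, then blur
    and add noise.  The PSF is applied on the sampled grid: for a rigid motion
    and an isotropic Gaussian the two operations commute."""
    shape = spec.grid_shape
    sp = np.asarray(spec.spacing)
    axes = [sp[a] * np.arange(shape[a]) for a in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if transform is not None:
        grid = transform.apply(grid)
    values = np.full(grid.shape[0], spec.background_suv)
    for les in spec.lesions:
        suv = les.suv_t1 if frame == 1 else les.suv_t2
        radius = les.radius if frame == 1 or les.radius_t2 is None else les.radius_t2
        d2 = np.sum((grid - np.asarray(les.center)) ** 2, axis=1)
        values[d2 <= radius**2] = suv
    values = values.reshape(shape)
    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / sp
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, size=shape)
    return np.clip(values, 0.0, None)


def generate_pair(spec: PhantomSpec):
    """Generate a (baseline, follow-up, ground truth) phantom triple.

    The follow-up volume lives in its own misaligned frame: its voxel at
    physical position x holds the tissue found at ``misalignment(x)`` in the
    baseline frame, so registration should recover ``spec.misalignment``.
    """
    _check_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    mis = spec.misalignment or RigidTransform.identity(
        center=tuple(e / 2 for e in spec.extent_mm)
    )
    baseline = PETVolume(
        values=_render_frame(spec, 1, None, rng),
        spacing=spec.spacing,
        frame_id="baseline",
    )
    identity = spec.misalignment is None or (
        np.allclose(mis.rotation, 0) and np.allclose(mis.translation, 0)
    )
    followup = PETVolume(
        values=_render_frame(spec, 2, None if identity else mis, rng),
        spacing=spec.spacing,
        frame_id="followup",
    )
    rows = []
    for i, les in enumerate(spec.lesions):
        change = les.true_change_pct
        rows.append(
            {
                "lesion_id": les.lesion_id or f"L{i + 1}",
                "organ": les.organ,
                "true_change_pct": change,
                "gold_label": "responder"
                if change <= spec.response_rule_threshold
                else "non_responder",
            }
        )
    lesions = pd.DataFrame(rows)
    patient = (
        "responder"
        if len(lesions) and (lesions["gold_label"] == "responder").all()
        else "non_responder"
    )
    truth = GroundTruth(
        lesions=lesions,
        patient_label=patient,
        misalignment=mis,
        response_rule_threshold=spec.response_rule_threshold,
    )
    return baseline, followup, truth


# ---------------------------------------------------------------------------
# cohort sampling


def _sample_organs(rng, n, used):
    organs = list(ORGAN_FREQUENCIES)
    probs = np.array([ORGAN_FREQUENCIES[o] for o in organs], dtype=float)
    probs /= probs.sum()
    out = []
    for _ in range(n):
        while True:
            organ = rng.choice(organs, p=probs)
            if used.get(organ, 0) < 2:  # PERCIST: at most two targets per organ
                used[organ] = used.get(organ, 0) + 1
                out.append(str(organ))
                break
    return out


def _place_centers(rng, n, extent, radii, margin=10.0, min_gap=30.0, max_tries=2000):
    """Rejection-sample lesion centers: inside the grid with a safety margin and
    with >= min_gap mm between lesion surfaces (keeps each lesion's working
    region and background shell free of its neighbours)."""
    centers = []
    for i in range(n):
        r = radii[i]
        lo = r + margin
        hi = np.asarray(extent) - r - margin
        if np.any(hi <= lo):
            raise ValueError("grid too small for requested lesion radius")
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(c - np.asarray(c2)) >= r + r2 + min_gap
                for c2, r2 in centers
            )
            if ok:
                centers.append((tuple(c), r))
                break
        else:
            raise RuntimeError("could not place lesions without crowding")
    return [c for c, _ in centers]


def sample_catalog(
    n_patients: int,
    response_mix: dict | None = None,
    seed: int = 0,
    grid_shape=(96, 96, 96),
    spacing=(2.0, 2.0, 2.0),
    misalign: bool = True,
    psf_fwhm: float = 6.0,
    noise_sigma: float = 0.15,
    background_suv: float = 2.0,
) -> list:
    """Sample per-patient :class:`PhantomSpec` objects (no voxel data yet)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = dict(DEFAULT_RESPONSE_MIX if response_mix is None else response_mix)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("response_mix proportions must sum to 1")
    unknown = set(classes) - set(RESPONSE_BANDS)
    if unknown:
        raise ValueError(f"unknown response classes: {unknown}")
    rng = np.random.default_rng(seed)
    extent = tuple((n - 1) * s for n, s in zip(grid_shape, spacing))
    specs = []
    for p in range(n_patients):
        n_lesions = int(rng.choice([1, 2], p=[0.45, 0.55]))
        radii = rng.uniform(8.0, 12.0, size=n_lesions)
        centers = _place_centers(rng, n_lesions, extent, radii)
        organs = _sample_organs(rng, n_lesions, {})
        lesions = []
        for j in range(n_lesions):
            suv1 = rng.uniform(5.0, 9.0)
            cls = classes[rng.choice(len(classes), p=probs)]
            lo, hi = RESPONSE_BANDS[cls]
            change = rng.uniform(lo, hi)
            lesions.append(
                LesionSpec(
                    center=centers[j],
                    radius=float(radii[j]),
                    suv_t1=float(suv1),
                    suv_t2=float(suv1 * (1.0 + change / 100.0)),
                    organ=organs[j],
                    lesion_id=f"P{p + 1:03d}-L{j + 1}",
                )
            )
        if misalign:
            mis = RigidTransform(
                rotation=tuple(np.radians(rng.uniform(-2.0, 2.0, size=3))),
                translation=tuple(rng.uniform(-4.0, 4.0, size=3)),
                center=tuple(e / 2 for e in extent),
            )
        else:
            mis = None
        specs.append(
            PhantomSpec(
                grid_shape=tuple(grid_shape),
                spacing=tuple(spacing),
                background_suv=background_suv,
                lesions=lesions,
                psf_fwhm=psf_fwhm,
                noise_sigma=noise_sigma,
                misalignment=mis,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


@dataclass
class Cohort:
    """A sampled phantom cohort: per-pair specs plus CSV-ready catalogs."""

    specs: list
    lesion_catalog: pd.DataFrame
    gold_standard: pd.DataFrame

    def __len__(self):
        return len(self.specs)

    def pairs(self):
        """Lazily generate (patient_id, pair_id, baseline, followup, truth)."""
        for i, spec in enumerate(self.specs):
            pid, pair = f"P{i + 1:03d}", f"pair{i + 1:03d}"
            baseline, followup, truth = generate_pair(spec)
            yield pid, pair, baseline, followup, truth

    def write(self, out_dir, volumes: bool = False):
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.lesion_catalog.to_csv(out / "lesion_catalog.csv", index=False)
        self.gold_standard.to_csv(out / "gold_standard.csv", index=False)
        if volumes:
            for pid, pair, b, f, _ in self.pairs():
                write_volume(b, out / f"{pid}_baseline.nii.gz")
                write_volume(f, out / f"{pid}_followup.nii.gz")


def generate_cohort(
    n_patients: int,
    response_mix: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> Cohort:
    """Sample a phantom cohort and build its lesion / gold-standard catalogs."""
    specs = sample_catalog(n_patients, response_mix=response_mix, seed=seed, **kwargs)
    lesion_rows, gold_rows = [], []
    for i, spec in enumerate(specs):
        pid, pair = f"P{i + 1:03d}", f"pair{i + 1:03d}"
        patient_resp = True
        for les in spec.lesions:
            seed_idx = np.rint(
                np.asarray(les.center) / np.asarray(spec.spacing)
            ).astype(int)
            label = (
                "responder"
                if les.true_change_pct <= spec.response_rule_threshold
                else "non_responder"
            )
            patient_resp &= label == "responder"
            lesion_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": les.lesion_id,
                    "organ": les.organ,
                    "seed_x": int(seed_idx[0]),
                    "seed_y": int(seed_idx[1]),
                    "seed_z": int(seed_idx[2]),
                    "pair_id": pair,
                    "gold_label": label,
                }
            )
        gold_rows.append(
            {
                "patient_id": pid,
                "pair_id": pair,
                "gold_label": "responder" if patient_resp else "non_responder",
            }
        )
    return Cohort(
        specs=specs,
        lesion_catalog=pd.DataFrame(lesion_rows),
        gold_standard=pd.DataFrame(gold_rows),
    )
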