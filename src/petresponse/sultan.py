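"""SULTAN: two-frame factor analysis producing a parametric change image.

Each voxel of a registered scan pair carries a two-sample kinetic
``S(v, .) = (S(v, 1), S(v, 2))`` modelled as

    S(v, t) = Ib(v) Cb(t) + Ie(v) Ce(t) + e(v, t)

with a constant background factor Cb and an evolution factor Ce (factor
analysis of dynamic sequences with K = 2, the number of scans).  The factor
image Ie localizes change; the SULTAN image keeps Ie where |Ie| exceeds a
significance cut (default 1) and zeroes it elsewhere.  Lesions are then
classified from the evolution direction and the sign of their Ie content.

Normalization making the fixed cut meaningful: Cb is the unit-norm constant
vector and Ce is unit-norm, so Ib and Ie carry SUV-scaled units and |Ie| > 1
corresponds to roughly 1.4 SUV of between-scan change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LesionVOI, PETVolume

__all__ = [
    "FadsConfig",
    "TwoFrameFactorAnalysis",
    "FactorAnalysisResults",
    "SultanImage",
    "sultan_image",
    "classify_lesion_sultan",
    "classify_patient_sultan",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class FadsConfig:
    tol: float = 1e-6
    max_iter: int = 20
    evolving_z: float = 3.0        # MAD multiples defining the evolving set
    degenerate_ratio: float = 1e-3  # s2/s1 below which the model is all-stable


@dataclass
class SultanImage:
    """The thresholded evolution-factor image."""

    values: np.ndarray
    threshold: float
    direction: str  # "decreasing" | "increasing" | "none"

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.values))


class TwoFrameFactorAnalysis:
    """Factor model of a registered baseline / follow-up pair.

    Parameters
    ----------
    baseline, followup : PETVolume
        Must share grid shape and spacing; the follow-up is expected to be
        resampled onto the baseline grid already.
    roi : boolean ndarray or sequence of (lo, hi) pairs, optional
        Analysis region.  Defaults to the whole grid intersected with the
        follow-up's resampling validity mask when present.
    config : FadsConfig, optional
    """

    def __init__(self, baseline: PETVolume, followup: PETVolume, roi=None,
                 config: FadsConfig | None = None):
        if baseline.shape != followup.shape or baseline.spacing != followup.spacing:
            raise ValueError("frames must share the same grid")
        self.baseline = baseline
        self.followup = followup
        self.config = config or FadsConfig()
        mask = np.ones(baseline.shape, dtype=bool)
        if roi is not None:
            roi_arr = np.asarray(roi)
            if roi_arr.dtype == bool and roi_arr.shape == baseline.shape:
                mask = roi_arr.copy()
            else:
                mask = np.zeros(baseline.shape, dtype=bool)
                mask[tuple(slice(int(lo), int(hi)) for lo, hi in roi)] = True
        if followup.validity is not None:
            mask &= followup.validity
        if not mask.any():
            raise ValueError("empty analysis roi")
        self.roi = mask

    def fit(self) -> "FactorAnalysisResults":
        cfg = self.config
        s1 = np.asarray(self.baseline.values, dtype=float)[self.roi]
        s2 = np.asarray(self.followup.values, dtype=float)[self.roi]
        X = np.column_stack([s1, s2])
        cb = np.array([1.0, 1.0]) / np.sqrt(2.0)

        # principal component analysis of the voxel x 2 data
        Xc = X - X.mean(axis=0)
        _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
        diff = s1 - s2
        rho = np.abs(diff) / np.sqrt(2.0)  # residual of the Cb-only fit
        med = np.median(diff)
        sigma = 1.4826 * np.median(np.abs(diff - med)) / np.sqrt(2.0)
        evolving = rho > cfg.evolving_z * sigma if sigma > 0 else rho > 0

        # degeneracy: no energy orthogonal to the constant factor (all-stable
        # pair).  The centered second singular value cannot be used directly:
        # noiseless two-population data is rank one yet genuinely evolving.
        s_perp = float(np.linalg.norm(diff)) / np.sqrt(2.0)
        degenerate = (
            svals[0] <= 0
            or s_perp < cfg.degenerate_ratio * svals[0]
            or evolving.sum() < 2
        )
        if degenerate:
            ib = (s1 + s2) / np.sqrt(2.0)
            return self._results(cb, np.array([1.0, -1.0]) / np.sqrt(2.0), ib,
                                 np.zeros_like(ib), evolving, sigma, True, 0)

        # oblique rotation: first factor pinned to the constant vector; the
        # evolution factor starts at the second principal component
        ce = vt[1] / np.linalg.norm(vt[1])
        n_iter = 0
        for n_iter in range(1, cfg.max_iter + 1):
            ib, ie = self._solve_images(X, cb, ce)
            # re-estimate Ce from the residual structure of the voxels poorly
            # explained by Cb alone: deflating Cb leaves a single direction in
            # two-frame data, oriented along the dominant evolution
            w = float(np.sum(s2[evolving] - s1[evolving]))
            ce_new = np.array([-1.0, 1.0]) / np.sqrt(2.0)
            if w < 0:
                ce_new = -ce_new
            if np.linalg.norm(ce_new - ce) < cfg.tol:
                ce = ce_new
                break
            ce = ce_new
        ib, ie = self._solve_images(X, cb, ce)
        return self._results(cb, ce, ib, ie, evolving, sigma, False, n_iter)

    @staticmethod
    def _solve_images(X, cb, ce):
        """Per-voxel least squares of (Ib, Ie) given the factors (exact for a
        nonsingular 2x2 system)."""
        M = np.column_stack([cb, ce])
        Minv = np.linalg.inv(M)
        sol = X @ Minv.T
        return sol[:, 0], sol[:, 1]

    def _results(self, cb, ce, ib, ie, evolving, sigma, degenerate, n_iter):
        def embed(flat):
            out = np.zeros(self.baseline.shape)
            out[self.roi] = flat
            return out

        s1 = np.asarray(self.baseline.values, dtype=float)[self.roi]
        s2 = np.asarray(self.followup.values, dtype=float)[self.roi]
        recon = np.column_stack([ib, ie]) @ np.column_stack([cb, ce]).T
        resid = np.sqrt(np.mean((np.column_stack([s1, s2]) - recon) ** 2, axis=1))
        return FactorAnalysisResults(
            model=self,
            c_b=cb,
            c_e=ce,
            i_b=embed(ib),
            i_e=embed(ie),
            residual_rms=embed(resid),
            roi=self.roi,
            evolving_fraction=float(np.mean(evolving)),
            noise_sigma=float(sigma),
            degenerate=bool(degenerate),
            n_iter=int(n_iter),
        )


@dataclass
class FactorAnalysisResults:
    """Fitted factors, factor images and diagnostics of a two-frame model."""

    model: TwoFrameFactorAnalysis
    c_b: np.ndarray
    c_e: np.ndarray
    i_b: np.ndarray
    i_e: np.ndarray
    residual_rms: np.ndarray
    roi: np.ndarray
    evolving_fraction: float
    noise_sigma: float
    degenerate: bool
    n_iter: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def direction(self) -> str:
        if self.degenerate:
            return "none"
        return "decreasing" if self.c_e[1] < self.c_e[0] else "increasing"

    def sultan_image(self, threshold: float = 1.0) -> SultanImage:
        """Apply the significance cut: Ie where |Ie| > threshold, else 0."""
        values = np.where(np.abs(self.i_e) > threshold, self.i_e, 0.0)
        return SultanImage(values=values, threshold=threshold, direction=self.direction)

    def summary(self) -> str:
        lines = [
            "Two-frame factor analysis (SULTAN)",
            "-" * 40,
            f"roi voxels          : {int(self.roi.sum())}",
            f"degenerate          : {self.degenerate}",
            f"direction of Ce     : {self.direction}",
            f"Cb                  : [{self.c_b[0]:.4f} {self.c_b[1]:.4f}]",
            f"Ce                  : [{self.c_e[0]:.4f} {self.c_e[1]:.4f}]",
            f"evolving fraction   : {self.evolving_fraction:.4%}",
            f"noise sigma (MAD)   : {self.noise_sigma:.4f} SUV",
            f"reconstruction RMS  : {float(self.residual_rms[self.roi].mean()):.3e}",
            f"iterations          : {self.n_iter}",
        ]
        return "\n".join(lines)


def sultan_image(results: FactorAnalysisResults, threshold: float = 1.0) -> SultanImage:
    """Functional alias of :meth:`FactorAnalysisResults.sultan_image`."""
    return results.sultan_image(threshold)


def classify_lesion_sultan(image: SultanImage, voi: LesionVOI) -> str:
    """Responder / non-responder call for one lesion.

    Responder when the significant Ie content of the lesion tracks a decrease:
    (Ce decreasing and Ie sum > 0) or (Ce increasing and Ie sum < 0).  A lesion
    with no significant voxels is a non-responder (no change).  Ie content is
    aggregated by sum so large coherent changes dominate speckle.
    """
    if voi.mask.shape != image.values.shape or not voi.mask.any():
        raise ValueError("lesion mask empty or misaligned with the SULTAN image")
    content = float(image.values[voi.mask].sum())
    if content == 0.0 or image.direction == "none":
        return NON_RESPONDER
    if image.direction == "decreasing":
        return RESPONDER if content > 0 else NON_RESPONDER
    return RESPONDER if content < 0 else NON_RESPONDER


def classify_patient_sultan(lesion_labels) -> str:
    """Patient rule: responder iff every lesion is a responder."""
    labels = list(lesion_labels)
    if not labels:
        raise ValueError("patient has no lesion classifications")
    return RESPONDER if all(l == RESPONDER for l in labels) else NON_RESPONDER
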