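"""Rigid block-matching registration of serial PET volumes.

The follow-up scan is aligned onto the baseline with a six-parameter rigid
transform estimated by iterated block matching: small image blocks are
displaced to maximize normalized cross-correlation within a search window,
a rigid transform is robust-fitted to the block displacement field by least
trimmed squares, the moving volume is resampled, and the procedure repeats
until the parameters stop changing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .volume import PETVolume, RigidTransform

__all__ = ["BlockMatchConfig", "register_rigid", "resample_through", "normalized_cross_correlation"]


@dataclass
class BlockMatchConfig:
    block_size: int = 5          # voxels per side
    search_radius: int = 5       # voxels
    block_stride: int = 2        # voxels between candidate block corners
    similarity: str = "ncc"
    trim_fraction: float = 0.2   # worst block matches discarded in the rigid fit
    max_iterations: int = 10
    convergence_tol: float = 0.1  # mm
    n_blocks: int = 256          # highest-contrast blocks kept per iteration

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.block_size < 3 or self.search_radius < 1:
            raise ValueError("block_size >= 3 and search_radius >= 1 required")
        if self.similarity != "ncc":
            raise ValueError("only normalized cross-correlation is supported")


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Global NCC of two equally shaped arrays (used for the no-harm check)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def resample_through(
    volume: PETVolume, transform: RigidTransform, reference: PETVolume
) -> PETVolume:
    """Resample ``volume`` onto ``reference``'s grid through ``transform``.

    ``transform`` maps points of ``volume``'s frame onto ``reference``'s frame;
    each reference voxel is trilinearly interpolated at the pre-image
    ``transform^-1(x)``.  Voxels mapping outside the source domain are zero and
    flagged in the returned volume's ``validity`` mask.
    """
    inv = transform.inverse()
    coords = reference.coordinate_grid().reshape(-1, 3)
    src = inv.apply(coords)
    idx = (src - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    shape = np.asarray(volume.shape)
    valid = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    sampled = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        idx.T,
        order=1,
        mode="constant",
        cval=0.0,
    )
    sampled[~valid] = 0.0
    return reference.with_values(
        np.clip(sampled.reshape(reference.shape), 0.0, None),
        frame_id=f"{volume.frame_id}~resampled",
        validity=valid.reshape(reference.shape),
    )


def _select_blocks(fixed: np.ndarray, cfg: BlockMatchConfig, roi, valid_margin):
    """Corner indices of the highest-contrast blocks, kept clear of the border
    so the search window always fits."""
    B, r, stride = cfg.block_size, cfg.search_radius, cfg.block_stride
    shape = np.asarray(fixed.shape)
    starts = [np.arange(r, shape[a] - B - r + 1, stride) for a in range(3)]
    if any(len(s) == 0 for s in starts):
        raise ValueError("volume too small for the requested block configuration")
    corners = np.stack(np.meshgrid(*starts, indexing="ij"), axis=-1).reshape(-1, 3)
    if roi is not None:
        centers = corners + B // 2
        inside = np.ones(len(corners), dtype=bool)
        for a in range(3):
            lo, hi = roi[a]
            inside &= (centers[:, a] >= lo) & (centers[:, a] < hi)
        corners = corners[inside]
        if len(corners) == 0:
            raise ValueError("roi contains no candidate blocks")
    windows = sliding_window_view(fixed, (B, B, B))
    stds = windows[tuple(corners.T)].reshape(len(corners), -1).std(axis=1)
    if valid_margin is not None:
        ok = valid_margin[tuple((corners + B // 2).T)]
        corners, stds = corners[ok], stds[ok]
    max_std = stds.max() if len(stds) else 0.0
    if max_std <= 0 or not np.isfinite(max_std):
        raise ValueError("degenerate input: no matchable blocks (constant image)")
    keep = stds > 0.1 * max_std
    corners, stds = corners[keep], stds[keep]
    order = np.argsort(stds)[::-1][: cfg.n_blocks]
    return corners[order]


def _parabolic_offset(c_minus, c0, c_plus):
    denom = c_minus - 2.0 * c0 + c_plus
    if denom >= -1e-12:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (c_minus - c_plus) / denom, -0.5, 0.5))


def _match_block(fixed_block, window, B, r):
    """Best displacement (voxels, float) of ``fixed_block`` within ``window``."""
    views = sliding_window_view(window, (B, B, B))  # (2r+1)^3 candidate blocks
    cand = views.reshape(-1, B**3).astype(float)
    fb = fixed_block.ravel().astype(float)
    fb = fb - fb.mean()
    fb_norm = np.linalg.norm(fb)
    cand = cand - cand.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cand, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = cand @ fb / np.where(norms * fb_norm > 0, norms * fb_norm, np.inf)
    ncc = ncc.reshape(2 * r + 1, 2 * r + 1, 2 * r + 1)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    disp = np.asarray(peak, dtype=float)
    for a in range(3):
        if 0 < peak[a] < 2 * r:
            lo = list(peak)
            hi = list(peak)
            lo[a] -= 1
            hi[a] += 1
            disp[a] += _parabolic_offset(ncc[tuple(lo)], ncc[tuple(peak)], ncc[tuple(hi)])
    return disp - r, float(ncc[peak])


def _fit_rigid_lts(source, target, center, trim_fraction):
    """Least-trimmed-squares rigid fit mapping source points onto target points."""
    keep = np.ones(len(source), dtype=bool)
    R, t = np.eye(3), np.zeros(3)
    for _ in range(3):
        s, tg = source[keep], target[keep]
        s_mean, t_mean = s.mean(axis=0), tg.mean(axis=0)
        H = (s - s_mean).T @ (tg - t_mean)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        t = t_mean - R @ s_mean
        res = np.linalg.norm(source @ R.T + t - target, axis=1)
        n_keep = max(3, int(np.ceil(len(source) * (1.0 - trim_fraction))))
        keep = np.zeros(len(source), dtype=bool)
        keep[np.argsort(res)[:n_keep]] = True
    return RigidTransform.from_matrix(R, t, center=center)


def register_rigid(
    fixed: PETVolume,
    moving: PETVolume,
    config: BlockMatchConfig | None = None,
    roi=None,
) -> RigidTransform:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    Parameters
    ----------
    fixed, moving : PETVolume
        Overlapping volumes; for phantom work the PET channel itself is used,
        while clinical practice would pass the anatomical (CT) channel and
        transfer the transform.
    config : BlockMatchConfig, optional
    roi : sequence of (lo, hi) index pairs, optional
        When given, only blocks whose centers lie inside the box contribute
        (local rigid registration of the region of interest).
    """
    cfg = config or BlockMatchConfig()
    if fixed.values.std() == 0 or moving.values.std() == 0:
        raise ValueError("degenerate input: constant image has no matchable blocks")
    B, r = cfg.block_size, cfg.search_radius
    center = tuple(fixed.physical_center)
    transform = RigidTransform.identity(center=center)
    fvals = np.asarray(fixed.values, dtype=float)
    spacing = np.asarray(fixed.spacing)
    prev_params = np.zeros(6)
    for iteration in range(cfg.max_iterations):
        if iteration == 0:
            mvals, validity = np.asarray(moving.values, dtype=float), None
        else:
            res = resample_through(moving, transform, fixed)
            mvals = np.asarray(res.values, dtype=float)
            validity = ndimage.binary_erosion(res.validity, iterations=r + 1)
        if validity is not None and not validity.any():
            raise ValueError("insufficient overlap between volumes")
        corners = _select_blocks(fvals, cfg, roi, validity)
        sources, targets = [], []
        for corner in corners:
            sl = tuple(slice(c, c + B) for c in corner)
            wsl = tuple(slice(c - r, c + B + r) for c in corner)
            disp, score = _match_block(fvals[sl], mvals[wsl], B, r)
            if not np.isfinite(score):
                continue
            p = (corner + (B - 1) / 2.0) * spacing + np.asarray(fixed.origin)
            sources.append(p + disp * spacing)
            targets.append(p)
        if len(sources) < 4:
            raise ValueError("insufficient overlap: too few usable block matches")
        delta = _fit_rigid_lts(
            np.asarray(sources), np.asarray(targets), center, cfg.trim_fraction
        )
        transform = delta.compose(transform)
        params = np.concatenate([transform.translation, transform.rotation])
        # parameter motion in mm: translation change plus rotation change at a
        # lever arm of half the smallest volume extent
        lever = 0.5 * min(np.asarray(fixed.shape) * spacing)
        change = np.linalg.norm(params[:3] - prev_params[:3]) + lever * np.linalg.norm(
            params[3:] - prev_params[3:]
        )
        prev_params = params
        if change < cfg.convergence_tol:
            break
    return transform
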