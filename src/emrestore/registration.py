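"""Coarse-to-fine alignment of paired acquisitions and patch tiling.

A short-dwell raw frame and its long-dwell reference are never pixel-aligned:
stage drift between the two passes adds a global projective component and
slow scan distortion adds a smooth local one.  Alignment therefore runs in
two stages, mirroring the physics:

1. *coarse*: ORB keypoints in both frames, Hamming matching with a ratio
   test, RANSAC projective fit, warp of the raw frame onto the reference;
2. *fine*: dense iterative Lucas-Kanade optical flow between the coarsely
   aligned frame and the reference, resampling through the flow field.

Aligned frames are tiled into fixed-size square patches (default 256 px at
stride 196) with an edge-snap policy: the final patch in each axis is placed
flush with the border so no pixels are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.registration import optical_flow_ilk
from skimage.transform import ProjectiveTransform, warp
from scipy.ndimage import map_coordinates

__all__ = [
    "RegistrationError",
    "AlignmentResult",
    "PatchGrid",
    "coarse_align",
    "fine_align",
    "crop_patches",
    "build_training_pairs",
]


class RegistrationError(RuntimeError):
    """Raised when a pair cannot be aligned; carries the match count."""

    def __init__(self, message: str, n_matches: int = 0):
        super().__init__(message)
        self.n_matches = n_matches


@dataclass
class AlignmentResult:
    homography: np.ndarray | None   # 3x3, (row, col) convention, raw -> ref
    flow_field: np.ndarray | None   # (2, H, W) displacement, (row, col)
    warped: np.ndarray
    n_matches: int
    residual: float                 # mean reprojection error / |flow|, px


_SWAP = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def _xy_to_rc(mat: np.ndarray) -> np.ndarray:
    """Convert a homography acting on (x, y) = (col, row) to (row, col)."""
    return _SWAP @ mat @ _SWAP


def coarse_align(raw: np.ndarray, reference: np.ndarray,
                 n_keypoints: int = 1500, max_ratio: float = 0.75,
                 residual_threshold: float = 3.0,
                 min_inlier_ratio: float = 0.2,
                 seed: int = 0) -> AlignmentResult:
    """Global projective registration of ``raw`` onto ``reference``.

    Detects ORB (binary) keypoints in both frames, matches them by Hamming
    distance with a Lowe ratio test, fits a homography by RANSAC at a 3-px
    inlier threshold and warps the raw frame into the reference frame.

    Raises :class:`RegistrationError` when fewer than 4 inlier matches
    survive or the inlier fraction is too low to trust the fit (the case for
    structureless pure-noise inputs).
    """
    raw = np.asarray(raw, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if raw.ndim != 2 or reference.ndim != 2:
        raise ValueError("coarse_align expects 2D images")

    detections = []
    for img in (raw, reference):
        orb = ORB(n_keypoints=n_keypoints)
        try:
            orb.detect_and_extract(img)
        except RuntimeError as exc:   # no keypoints at all
            raise RegistrationError(f"keypoint detection failed: {exc}",
                                    n_matches=0) from exc
        detections.append((orb.keypoints, orb.descriptors))
    (kp_raw, d_raw), (kp_ref, d_ref) = detections

    matches = match_descriptors(d_raw, d_ref, cross_check=True,
                                max_ratio=max_ratio)
    if len(matches) < 4:
        raise RegistrationError(
            f"only {len(matches)} keypoint matches", n_matches=len(matches))

    src = kp_raw[matches[:, 0]][:, ::-1]   # (x, y) for the transform
    dst = kp_ref[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst), ProjectiveTransform, min_samples=4,
        residual_threshold=residual_threshold, max_trials=2000,
        rng=np.random.default_rng(seed),
    )
    n_inliers = 0 if inliers is None else int(inliers.sum())
    if (model is None or n_inliers < 4
            or not np.all(np.isfinite(model.params))
            or n_inliers < min_inlier_ratio * len(matches)):
        raise RegistrationError(
            f"homography fit rejected ({n_inliers} inliers of "
            f"{len(matches)} matches)", n_matches=n_inliers)

    # sub-pixel refinement: iterative least-squares refits on ever tighter
    # inlier sets (ORB corner localisation is ~1 px; averaging many
    # matches is not enough while RANSAC keeps 3-px stragglers)
    for thresh in (1.5, 1.0, 0.7, 0.5):
        err = np.sqrt(((model(src) - dst) ** 2).sum(axis=1))
        tight = err < thresh
        if tight.sum() < 8:
            break
        refit = ProjectiveTransform.from_estimate(src[tight], dst[tight])
        if not (refit and np.all(np.isfinite(refit.params))):
            break
        model = refit
        inliers = tight

    residual = float(np.sqrt(
        ((model(src[inliers]) - dst[inliers]) ** 2).sum(axis=1)).mean())
    # warp: output lives in the reference frame; map its coords back to raw
    warped = warp(raw, model.inverse, order=3, mode="reflect",
                  preserve_range=True)
    return AlignmentResult(
        homography=_xy_to_rc(model.params), flow_field=None, warped=warped,
        n_matches=n_inliers, residual=residual)


def fine_align(coarse_warped: np.ndarray, reference: np.ndarray,
               radius: int = 8) -> AlignmentResult:
    """Dense local alignment of an already coarsely aligned frame.

    Estimates iterative-Lucas-Kanade optical flow from the reference to the
    moving frame and resamples the moving frame through the field.  The
    returned ``residual`` is the mean flow magnitude before resampling.
    """
    moving = np.asarray(coarse_warped, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2:
        raise ValueError(
            f"shape mismatch: {moving.shape} vs {reference.shape}")
    flow = optical_flow_ilk(reference, moving, radius=radius)
    rows, cols = np.mgrid[0:moving.shape[0], 0:moving.shape[1]].astype(float)
    warped = map_coordinates(moving,
                             np.stack([rows + flow[0], cols + flow[1]]),
                             order=3, mode="reflect")
    residual = float(np.hypot(flow[0], flow[1]).mean())
    return AlignmentResult(homography=None, flow_field=flow, warped=warped,
                           n_matches=0, residual=residual)


@dataclass
class PatchGrid:
    """Row-major grid of full-size square patches inside ``source_shape``."""

    patch_size: int = 256
    stride: int = 196
    origins: list[tuple[int, int]] = field(default_factory=list)
    source_shape: tuple[int, int] = (0, 0)


def _axis_origins(dim: int, size: int, stride: int) -> list[int]:
    origins = list(range(0, dim - size + 1, stride))
    if origins[-1] + size < dim:       # edge-snap: flush final patch
        origins.append(dim - size)
    return origins


def crop_patches(image: np.ndarray, patch_size: int = 256,
                 stride: int = 196) -> tuple[PatchGrid, list[np.ndarray]]:
    """Tile ``image`` into full-size patches with the edge-snap policy."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} smaller than patch size {patch_size}")
    rows = _axis_origins(h, patch_size, stride)
    cols = _axis_origins(w, patch_size, stride)
    origins = [(r, c) for r in rows for c in cols]
    patches = [image[r:r + patch_size, c:c + patch_size]
               for r, c in origins]
    return PatchGrid(patch_size=patch_size, stride=stride, origins=origins,
                     source_shape=(h, w)), patches


def build_training_pairs(raw_list, reference_list, patch_size: int = 256,
                         stride: int = 196) -> dict:
    """Align each raw frame to its reference and tile both identically.

    Returns a dict with ``raw_patches``, ``reference_patches`` (parallel
    lists), a per-frame ``manifest`` (homography, residuals) and the indices
    of pairs that failed coarse alignment and were ``skipped``.
    """
    if len(raw_list) != len(reference_list):
        raise ValueError("raw and reference lists must pair 1:1")
    raw_patches, ref_patches, manifest, skipped = [], [], [], []
    for i, (rawi, refi) in enumerate(zip(raw_list, reference_list)):
        try:
            coarse = coarse_align(rawi, refi)
        except RegistrationError as exc:
            skipped.append((i, exc.n_matches))
            continue
        fine = fine_align(coarse.warped, refi)
        grid, aligned = crop_patches(fine.warped, patch_size, stride)
        _, refs = crop_patches(np.asarray(refi, dtype=float),
                               patch_size, stride)
        raw_patches.extend(aligned)
        ref_patches.extend(refs)
        manifest.append({
            "pair": i,
            "homography": coarse.homography.ravel().tolist(),
            "coarse_residual": coarse.residual,
            "fine_residual": fine.residual,
            "n_matches": coarse.n_matches,
            "grid": grid,
        })
    return {"raw_patches": raw_patches, "reference_patches": ref_patches,
            "manifest": manifest, "skipped": skipped}
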