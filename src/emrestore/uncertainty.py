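"""Ensemble-based reliability self-assessment of restored images.

Restoration from noisy data is ill-posed: the diffusion model can draw many
plausible solutions for one input.  Where K independent draws agree the
prediction is trustworthy; where they diverge it is not.  The per-pixel
standard deviation of the K draws (after per-patch min-max normalization,
which makes the score invariant to the local intensity range) is the
epistemic uncertainty map delta; a patch's scalar uncertainty value U is the
99th percentile of its delta values — the top 1% of pixels are disregarded
because isolated high-contrast membrane pixels produce large but harmless
deviations.  A patch is flagged unreliable when U exceeds the threshold tau
(default 0.12), and an image is flagged when any of its patches is.

``calibrate_threshold`` re-derives tau for a new dataset from (U, quality
score) pairs: the quality histogram of a mixed good/bad prediction set is
bimodal, and tau is the mean U of the samples sitting in the valley between
the two modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "UncertaintyReport",
    "CalibrationError",
    "minmax_normalize",
    "ensemble_std",
    "patch_uncertainty",
    "assess_image",
    "calibrate_threshold",
    "DEFAULT_TAU",
    "DEFAULT_PERCENTILE",
]

DEFAULT_TAU = 0.12
DEFAULT_PERCENTILE = 99.0


class CalibrationError(RuntimeError):
    """Raised when the quality distribution has no two-mode valley."""


@dataclass
class UncertaintyReport:
    patch_values: list[float]
    origins: list[tuple[int, int]]
    tau: float
    percentile: float
    patch_flags: list[bool]
    image_flag: bool
    image_value: float = field(default=0.0)   # max patch U

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "percentile": self.percentile,
            "image_flag": self.image_flag,
            "image_value": self.image_value,
            "patches": [
                {"origin": list(o), "U": u, "unreliable": f}
                for o, u, f in zip(self.origins, self.patch_values,
                                   self.patch_flags)
            ],
        }


def minmax_normalize(a: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a flat array maps to all zeros (no divide-by-zero)."""
    a = np.asarray(a, dtype=float)
    lo, hi = a.min(), a.max()
    if hi - lo == 0:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def ensemble_std(samples: np.ndarray, normalize: bool = True) -> np.ndarray:
    """delta = sqrt(sum_m (x^m - mean)^2 / (K-1)) over the K samples.

    ``samples`` has shape (K, ...); with ``normalize`` each sample is
    min-max normalized first (the convention used for uncertainty scoring).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("ensemble standard deviation needs K >= 2 samples")
    if normalize:
        samples = np.stack([minmax_normalize(s) for s in samples])
    return samples.std(axis=0, ddof=1)


def patch_uncertainty(delta: np.ndarray,
                      percentile: float = DEFAULT_PERCENTILE) -> float:
    """U = the given percentile (linear interpolation) of the delta map."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty uncertainty patch")
    return float(np.percentile(delta, percentile, method="linear"))


def assess_image(samples: np.ndarray, grid, tau: float = DEFAULT_TAU,
                 percentile: float = DEFAULT_PERCENTILE) -> UncertaintyReport:
    """Patchwise reliability report for a full image.

    ``samples`` is the (K, H, W) stack of whole-image restorations and
    ``grid`` a :class:`~emrestore.registration.PatchGrid`.  Each patch of
    each sample is min-max normalized, delta is the K-sample SD, U its
    ``percentile`` value; patches with U > tau are flagged and the image is
    flagged iff any patch is.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[0] < 2:
        raise ValueError("assess_image needs a (K>=2, H, W) sample stack")
    s = grid.patch_size
    values, flags = [], []
    for r, c in grid.origins:
        delta = ensemble_std(samples[:, r:r + s, c:c + s])
        u = patch_uncertainty(delta, percentile)
        values.append(u)
        flags.append(u > tau)
    return UncertaintyReport(
        patch_values=values, origins=list(grid.origins), tau=tau,
        percentile=percentile, patch_flags=flags,
        image_flag=bool(any(flags)),
        image_value=float(max(values)) if values else 0.0)


def calibrate_threshold(pairs, n_bins: int = 32,
                        smooth_sigma: float = 1.5) -> float:
    """Derive tau from (U, quality score) pairs of scored predictions.

    The quality scores are histogrammed (``n_bins`` bins, Gaussian-smoothed);
    the valley is the minimum between the two largest modes, and tau is the
    mean U of the samples whose score falls within half a bin of the valley
    centre.  Raises :class:`CalibrationError` when the smoothed histogram is
    unimodal — in that case there is no good/bad transition to calibrate on.
    """
    pairs = [(float(u), float(q)) for u, q in pairs]
    if len(pairs) < 20:
        raise ValueError(
            f"calibration needs >= 20 scored predictions, got {len(pairs)}")
    us = np.array([p[0] for p in pairs])
    qs = np.array([p[1] for p in pairs])
    hist, edges = np.histogram(qs, bins=n_bins)
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma)

    interior = (smooth >= np.roll(smooth, 1)) & (smooth >= np.roll(smooth, -1))
    interior[0] = smooth[0] > smooth[1]
    interior[-1] = smooth[-1] > smooth[-2]
    # only peaks comparable to the dominant mode count as modes
    peaks = np.flatnonzero(interior & (smooth >= 0.2 * smooth.max()))
    if len(peaks) < 2:
        raise CalibrationError("quality distribution is unimodal")
    top = peaks[np.argsort(smooth[peaks])][-2:]
    lo, hi = sorted(top)
    if hi - lo < 2:
        raise CalibrationError("quality modes are not separated")
    between = smooth[lo:hi + 1]
    plateau = np.flatnonzero(between == between.min())
    valley_bin = lo + int(plateau[len(plateau) // 2])  # centre of plateau
    valley_val = smooth[valley_bin]
    if valley_val > 0.5 * min(smooth[lo], smooth[hi]):
        raise CalibrationError(
            "no clear valley between the quality modes")
    centers = (edges[:-1] + edges[1:]) / 2.0
    half_bin = (edges[1] - edges[0]) / 2.0
    near = np.abs(qs - centers[valley_bin]) <= half_bin
    if not near.any():
        # sparse transition region: fall back to the closest scored samples
        dist = np.abs(qs - centers[valley_bin])
        near = dist <= np.sort(dist)[1]
    return float(us[near].mean())
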