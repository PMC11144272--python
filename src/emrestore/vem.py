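"""Isotropic reconstruction of anisotropic volume-EM stacks.

Serial-section volume EM delivers stacks whose axial (z) voxel size is much
coarser than the lateral one (e.g. 8 x 8 x 48 nm).  The slice-interpolation
model here generates the R missing layers between every pair of adjacent
acquired layers with a conditional diffusion network that receives both
bounding layers plus a sinusoidal *channel embedding* of the target index
j in [1, R]; R is the axial/lateral voxel ratio minus one.

Two training regimes share the same index arithmetic (1-based layer indices,
matching the construction rule c^l = c^(u+R+1), targets x0^(u+1..u+R)):

* *isotropic-supervised* ("-i"): training pairs are cut along z from a small
  isotropic volume; inference runs on an anisotropic stack.
* *anisotropic-only* ("-a"): no isotropic data exists, so training pairs are
  cut along y — the XZ views of the anisotropic volume stand in for the
  missing fine-z supervision (lateral structure statistics transfer to the
  axial axis); training is capped (default 1200 epochs) because long runs
  overfit to the line artifacts those views carry.

A per-column cubic-spline interpolation along z is provided as the classical
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.interpolate import CubicSpline

from . import diffusion, uncertainty

__all__ = [
    "ANISO_MAX_EPOCHS",
    "VolumeSpec",
    "VemTrainingSample",
    "downsample_axial",
    "build_training_samples_i",
    "build_training_samples_a",
    "as_diffusion_samples",
    "infer_isotropic",
    "cubic_baseline",
]


#: Epoch cap for anisotropic-only training: the XZ training views carry
#: line artifacts, and long runs overfit to them.
ANISO_MAX_EPOCHS = 1200


@dataclass
class VolumeSpec:
    """3D grayscale stack indexed (z, y, x) with voxel sizes in nm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (8.0, 8.0, 8.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("volume must be 3D with every dim >= 2")

    @property
    def M(self) -> int:
        """Number of z layers."""
        return self.data.shape[0]

    @property
    def R(self) -> int:
        """Interpolation count: axial/lateral voxel ratio minus one."""
        return max(0, int(round(self.voxel_size[0] / self.voxel_size[2])) - 1)


@dataclass
class VemTrainingSample:
    """Upper/lower conditioning slices and the R target slices between."""

    upper: np.ndarray                    # c^u
    lower: np.ndarray                    # c^l = c^(u+R+1)
    targets: list[np.ndarray] = field(default_factory=list)
    axis: str = "z"
    u: int = 1                           # 1-based anchor index


def downsample_axial(volume: VolumeSpec, factor: int) -> VolumeSpec:
    """Simulate an anisotropic acquisition by mod-``factor`` layer removal.

    Keeps the 1-based layer indices j with ``j mod factor == 1`` (for the
    reference factor 6 this turns an 8-nm axial step into 48 nm) and scales
    the axial voxel size accordingly.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    kept = volume.data[::factor]  # 1-based j % f == 1  <=>  0-based i % f == 0
    z, y, x = volume.voxel_size
    return VolumeSpec(data=kept.copy(), voxel_size=(z * factor, y, x))


def _anchor_samples(get_slice, n_layers: int, R: int, axis: str
                    ) -> Iterator[VemTrainingSample]:
    for u in range(1, n_layers - R):          # 1-based; u + R + 1 <= n_layers
        yield VemTrainingSample(
            upper=get_slice(u - 1),
            lower=get_slice(u + R),           # 0-based index of c^(u+R+1)
            targets=[get_slice(u - 1 + j) for j in range(1, R + 1)],
            axis=axis, u=u)


def build_training_samples_i(volume: VolumeSpec, R: int
                             ) -> list[VemTrainingSample]:
    """Training pairs cut along z from an isotropic volume.

    Anchor u runs over every layer with u + R + 1 <= M; the sample bounds
    layers u and u+R+1 and targets the R layers between them.
    """
    if R < 1:
        raise ValueError("R must be >= 1: no layers to interpolate")
    if volume.M < R + 2:
        raise ValueError(
            f"volume has {volume.M} layers; need at least R + 2 = {R + 2}")
    return list(_anchor_samples(lambda i: volume.data[i], volume.M, R, "z"))


def build_training_samples_a(volume: VolumeSpec, R: int
                             ) -> list[VemTrainingSample]:
    """Training pairs cut along y from an anisotropic volume.

    Identical index arithmetic to the isotropic-supervised construction but
    the slices are (Z, X) views taken along y; the model trained on them is
    applied along z at inference.
    """
    if R < 1:
        raise ValueError("R must be >= 1: no layers to interpolate")
    n_y = volume.data.shape[1]
    if n_y < R + 2:
        raise ValueError(
            f"volume has {n_y} y-lines; need at least R + 2 = {R + 2}")
    return list(_anchor_samples(lambda i: volume.data[:, i, :], n_y, R, "y"))


def as_diffusion_samples(samples: list[VemTrainingSample],
                         vmin: float = 0.0, vmax: float = 1.0
                         ) -> list[diffusion.DiffusionSample]:
    """Flatten (sample, j) pairs into conditional diffusion samples.

    Intensities are mapped to [-1, 1] with a per-volume (not per-slice)
    window so adjacent generated layers share one scale.
    """
    span = vmax - vmin
    if span <= 0:
        raise ValueError("vmax must exceed vmin")

    def nrm(a):
        return diffusion.to_model_range((a - vmin) / span)

    out = []
    for s in samples:
        cond = np.stack([nrm(s.upper), nrm(s.lower)])
        for j, target in enumerate(s.targets, start=1):
            out.append(diffusion.DiffusionSample(x0=nrm(target), cond=cond,
                                                 j=j))
    return out


def infer_isotropic(volume: VolumeSpec, net, schedule, K: int = 2,
                    seed: int = 0, tau: float = uncertainty.DEFAULT_TAU,
                    vmin: float = 0.0, vmax: float = 1.0
                    ) -> tuple[VolumeSpec, list]:
    """Interleave R generated layers between every adjacent input pair.

    Traverses the adjacent pairs (c^u, c^(u+1)) of the M input layers; for
    each pair the network generates layers j = 1..R (channel-embedded),
    averaging K draws per layer.  The output stack has M + (M-1)*R layers
    and an axial voxel size divided by (R + 1).  Returns the volume plus one
    (z_index, U, flag) record per generated layer (K >= 2 only).
    """
    if volume.M < 2:
        raise ValueError("need at least 2 input layers")
    R = volume.R
    if R == 0:
        return VolumeSpec(data=volume.data.copy(),
                          voxel_size=volume.voxel_size), []
    span = vmax - vmin
    layers: list[np.ndarray] = []
    reports = []
    for u in range(volume.M - 1):                       # zero-based pairs
        upper = diffusion.to_model_range((volume.data[u] - vmin) / span)
        lower = diffusion.to_model_range((volume.data[u + 1] - vmin) / span)
        cond = np.stack([upper, lower])
        layers.append(volume.data[u])
        for j in range(1, R + 1):
            seeds = [seed + (u * R + j) * K + m for m in range(K)]
            draws = np.stack([
                diffusion.sample(cond, j, net, schedule, seed=s)
                for s in seeds])
            mean = draws.mean(axis=0)
            layers.append(
                vmin + diffusion.from_model_range(mean) * span)
            if K >= 2:
                delta = uncertainty.ensemble_std(
                    np.stack([diffusion.from_model_range(d) for d in draws]))
                uval = uncertainty.patch_uncertainty(delta)
                reports.append({"z_index": len(layers) - 1, "U": uval,
                                "unreliable": uval > tau})
    layers.append(volume.data[-1])
    z, y, x = volume.voxel_size
    out = VolumeSpec(data=np.stack(layers),
                     voxel_size=(z / (R + 1), y, x))
    return out, reports


def cubic_baseline(volume: VolumeSpec, factor: int) -> VolumeSpec:
    """Classical per-column cubic-spline interpolation along z.

    Interpolates the M coarse layers onto the fine grid with ``factor - 1``
    new layers between each adjacent pair (matching the slice positions the
    diffusion model fills in), so the output has M + (M-1)*(factor-1)
    layers.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if volume.M < 4:
        raise ValueError("cubic interpolation needs at least 4 layers")
    if factor == 1:
        return VolumeSpec(data=volume.data.copy(),
                          voxel_size=volume.voxel_size)
    coarse_z = np.arange(volume.M, dtype=float)
    fine_z = np.arange((volume.M - 1) * factor + 1, dtype=float) / factor
    spline = CubicSpline(coarse_z, volume.data, axis=0)
    z, y, x = volume.voxel_size
    return VolumeSpec(data=spline(fine_z), voxel_size=(z / factor, y, x))
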