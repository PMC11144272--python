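"""Image/volume I/O and run configuration.

Images travel as 8/16-bit grayscale TIFF or PNG; predictions are written as
16-bit TIFF.  Volumes are multi-page TIFF or HDF5 (dataset ``volume`` with a
``voxel_size_nm`` attribute), axis order (z, y, x).  All layer/pixel
indexing inside the package is zero-based; the 1-based layer conventions of
the slice-construction rules live only in :mod:`emrestore.vem` docstrings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

from .vem import VolumeSpec

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
]


@dataclass
class RunConfig:
    """Defaults for a restoration run; every field is overridable."""

    task: str = "denoise"        # denoise | super_resolve | vem_i | vem_a
    model: str | None = None     # checkpoint path
    K: int = 2
    tau: float = 0.12
    patch_size: int = 256
    stride: int = 196
    seed: int = 0
    T: int = 1000
    sr_scale: float = 2.0
    axial_factor: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)

    def to_dict(self) -> dict:
        return asdict(self)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1].

    RGB inputs are averaged to grayscale with a warning; 8- and 16-bit
    integer and float images are supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: RGB input converted to grayscale")
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def write_image(path: str | Path, image: np.ndarray,
                dtype=np.uint16) -> Path:
    """Write a [0, 1] image as 16-bit TIFF (or 8-bit PNG by extension)."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(np.round(image * 255).astype(np.uint8)).save(path)
    else:
        if dtype == np.float32:
            tifffile.imwrite(path, image.astype(np.float32))
        else:
            tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    return path


def write_volume(path: str | Path, volume: VolumeSpec) -> Path:
    """Write a volume as multi-page TIFF (.tif) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.data)
            ds.attrs["voxel_size_nm"] = np.asarray(volume.voxel_size)
    else:
        tifffile.imwrite(
            path, np.round(np.clip(volume.data, 0, 1) * 65535
                           ).astype(np.uint16),
            photometric="minisblack",
            description=json.dumps(
                {"voxel_size_nm": list(volume.voxel_size)}))
    return path


def read_volume(path: str | Path) -> VolumeSpec:
    """Read a (z, y, x) volume with voxel-size metadata.

    Missing voxel-size metadata falls back to (1, 1, 1) nm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    voxel = None
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            data = f["volume"][...]
            if "voxel_size_nm" in f["volume"].attrs:
                voxel = tuple(float(v)
                              for v in f["volume"].attrs["voxel_size_nm"])
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
            if desc:
                try:
                    voxel = tuple(json.loads(desc)["voxel_size_nm"])
                except (json.JSONDecodeError, KeyError, TypeError):
                    voxel = None
    if data.dtype == np.uint16:
        data = data.astype(float) / 65535.0
    elif data.dtype == np.uint8:
        data = data.astype(float) / 255.0
    else:
        data = data.astype(float)
    if voxel is None:
        warnings.warn(f"{path.name}: no voxel size metadata, using 1 nm")
        voxel = (1.0, 1.0, 1.0)
    return VolumeSpec(data=data, voxel_size=voxel)
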